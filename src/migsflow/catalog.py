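"""Registry of the studied drainage devices and user-defined variants.

Built-ins are the three subconjunctival MIGS tubes of the study: the two
XEN gel stents (45 and 63 µm lumens, 6 mm long) and the PreserFlo
MicroShunt (70 µm, 8.5 mm).  Lookup is tolerant to spacing, dashes and
case, so "XEN 45", "xen-45" and "XEN45" name the same device.  Shortened
variants (the 1 mm-trimmed tubes of the length-sensitivity analysis) are
derived with :func:`shorten`.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List

from .hydraulics import ImplantSpec

__all__ = ["BUILTIN_DEVICES", "get_device", "list_devices", "shorten", "register_device"]


def _normalize(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalnum())


BUILTIN_DEVICES: Dict[str, ImplantSpec] = {
    "xen45": ImplantSpec("XEN 45", lumen_diameter_um=45.0, length_mm=6.0,
                         wall_thickness_um=150.0),
    "xen63": ImplantSpec("XEN 63", lumen_diameter_um=63.0, length_mm=6.0,
                         wall_thickness_um=220.0),
    "preserflo": ImplantSpec("PreserFlo", lumen_diameter_um=70.0, length_mm=8.5,
                             wall_thickness_um=350.0),
}

_registry: Dict[str, ImplantSpec] = dict(BUILTIN_DEVICES)
_provenance: Dict[str, str] = {k: "built-in" for k in BUILTIN_DEVICES}


def get_device(name: str) -> ImplantSpec:
    """Return a copy of the registered device; mutation never alters the registry."""
    key = _normalize(name)
    try:
        spec = _registry[key]
    except KeyError:
        available = ", ".join(sorted(_registry))
        raise KeyError(f"unknown device {name!r}; available: {available}") from None
    return replace(spec)


def list_devices() -> List[ImplantSpec]:
    """All registered devices, built-ins first."""
    return [replace(v) for v in _registry.values()]


def provenance(name: str) -> str:
    return _provenance[_normalize(name)]


def register_device(spec: ImplantSpec) -> None:
    """Register a user-defined device under its normalized name."""
    key = _normalize(spec.name)
    if key in BUILTIN_DEVICES:
        raise ValueError(f"cannot overwrite built-in device {spec.name!r}")
    _registry[key] = replace(spec)
    _provenance[key] = "user"


def shorten(implant: ImplantSpec, delta_mm: float) -> ImplantSpec:
    """Variant of ``implant`` with the tube trimmed by ``delta_mm``.

    Only the total length changes; the name is suffixed with the new
    length so that e.g. a 1 mm-trimmed XEN 45 reads "XEN 45-5mm".
    """
    if delta_mm < 0:
        raise ValueError("trim length must be non-negative")
    if delta_mm >= implant.length_mm:
        raise ValueError(
            f"cannot trim {delta_mm} mm from a {implant.length_mm} mm tube"
        )
    if delta_mm == 0:
        return replace(implant)
    new_len = implant.length_mm - delta_mm
    return replace(implant, length_mm=new_len, name=f"{implant.name}-{new_len:g}mm")
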