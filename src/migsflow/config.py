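"""YAML configuration loading.

A config file has up to three blocks::

    eye:
      p_g: 30            # mmHg, baseline IOP
      p_ev: 10.5         # mmHg, Schlemm-exit pressure
      Q_cb: 2.0          # ul/min, ciliary inflow
      uveoscleral_fraction: 0.15
      viscosity_pa_s: 7.0e-4
      density: 998.2
    device:
      name: XEN 45       # catalog lookup; or explicit geometry:
      # lumen_diameter_um: 45
      # length_mm: 6
      # shape_factor: 1
    bleb:
      mode: fixed_pressure   # or resistance
      p_b: 10                # mmHg        (fixed_pressure)
      # R_b: 5.0             # mmHg/(ul/min)  (resistance)
      # p_r: 0.0

Explicit geometry and a catalog name may be combined: explicit fields
override the catalog entry.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any, Dict, Optional, TextIO, Tuple, Union

import yaml

from .catalog import get_device
from .hydraulics import BlebState, EyeParameters, ImplantSpec

__all__ = ["load_config", "parse_config", "eye_from_block", "device_from_block",
           "bleb_from_block", "config_from_device"]


def eye_from_block(block: Dict[str, Any]) -> EyeParameters:
    return EyeParameters(
        p_g=float(block["p_g"]),
        p_ev=float(block.get("p_ev", 10.5)),
        Q_cb=float(block.get("Q_cb", 2.0)),
        uveoscleral_fraction=float(block.get("uveoscleral_fraction", 0.15)),
        viscosity=float(block.get("viscosity_pa_s", 7e-4)),
        density=float(block.get("density", 998.2)),
    )


def device_from_block(block: Dict[str, Any]) -> ImplantSpec:
    if "name" in block and "lumen_diameter_um" not in block:
        spec = get_device(block["name"])
    elif "name" in block:
        spec = get_device(block["name"]) if _is_registered(block["name"]) else None
        base = dict(
            name=block["name"],
            lumen_diameter_um=float(block["lumen_diameter_um"]),
            length_mm=float(block["length_mm"]),
            shape_factor=float(block.get("shape_factor", 1.0)),
        )
        return ImplantSpec(**base) if spec is None else replace(spec, **base)
    else:
        return ImplantSpec(
            name=str(block.get("label", "custom")),
            lumen_diameter_um=float(block["lumen_diameter_um"]),
            length_mm=float(block["length_mm"]),
            shape_factor=float(block.get("shape_factor", 1.0)),
        )
    overrides = {}
    if "shape_factor" in block:
        overrides["shape_factor"] = float(block["shape_factor"])
    if "length_mm" in block:
        overrides["length_mm"] = float(block["length_mm"])
    return replace(spec, **overrides) if overrides else spec


def _is_registered(name: str) -> bool:
    try:
        get_device(name)
        return True
    except KeyError:
        return False


def bleb_from_block(block: Dict[str, Any]) -> BlebState:
    mode = block.get("mode", "fixed_pressure")
    if mode == "fixed_pressure":
        return BlebState.fixed(float(block["p_b"]))
    if mode == "resistance":
        return BlebState.resistive(float(block["R_b"]), float(block.get("p_r", 0.0)))
    raise ValueError(f"unknown bleb mode {mode!r}")


def parse_config(
    doc: Dict[str, Any]
) -> Tuple[EyeParameters, Optional[ImplantSpec], Optional[BlebState]]:
    eye = eye_from_block(doc["eye"])
    device = device_from_block(doc["device"]) if "device" in doc else None
    bleb = bleb_from_block(doc["bleb"]) if "bleb" in doc else None
    return eye, device, bleb


def load_config(source: Union[str, TextIO]):
    """Parse a YAML config file (path or open handle)."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    return parse_config(doc)


def config_from_device(spec: ImplantSpec) -> Dict[str, Any]:
    """Serialize a device back to a config block (round-trips exactly)."""
    block: Dict[str, Any] = {
        "name": spec.name,
        "lumen_diameter_um": spec.lumen_diameter_um,
        "length_mm": spec.length_mm,
        "shape_factor": spec.shape_factor,
    }
    return block
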