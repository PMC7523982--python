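"""Unit conversions between clinical and SI quantities.

All public interfaces of the package speak clinical units — pressures in
mmHg, flows in µl/min, lumen diameters in µm, tube lengths in mm — while
hydraulic resistances are formed in SI and converted once.  The constants
here are the single source of truth for those conversions.
"""

from __future__ import annotations

#: Pascals per mmHg.
MMHG_TO_PA: float = 133.322

#: Cubic metres per second per (µl/min).
ULMIN_TO_M3S: float = 1e-9 / 60.0

#: SI resistance (Pa·s·m⁻³) per clinical resistance unit (mmHg per µl/min).
CLINICAL_RESISTANCE_TO_SI: float = MMHG_TO_PA / ULMIN_TO_M3S


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_TO_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_TO_PA


def ulmin_to_m3s(q: float) -> float:
    return q * ULMIN_TO_M3S


def m3s_to_ulmin(q: float) -> float:
    return q / ULMIN_TO_M3S
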