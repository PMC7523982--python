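"""Steady-state hydraulics of aqueous outflow after microshunt implantation.

The model is a two-path resistor network.  Aqueous humor enters the anterior
chamber at a constant net rate Q_0 (ciliary production minus the uveoscleral
fraction) and leaves through two parallel paths:

* the natural trabecular meshwork / Schlemm's canal route, lumped into a
  single resistance R_t calibrated so that the preoperative pressures are
  recovered (R_t = (p_g − p_ev)/Q_0), and

* the implanted drainage tube, a laminar Hagen–Poiseuille resistance
  R_v = 128·L·Lv·µ/(π·Dh⁴) discharging into the filtration bleb at
  pressure p_b.

Flow conservation at the anterior chamber then fixes the postoperative
IOP p_c in closed form.  The bleb itself may be described either by an
imposed pressure (the early/late scarring scenarios) or by its own
hydraulic resistance R_b to the subconjunctival capillaries, in which case
the three-resistor chain is solved exactly.

Reynolds numbers in the tube are O(1) or less at physiological flows, so
the linear (creeping-flow) resistances are a faithful description; the
model deliberately ignores any dependence of inflow or outflow facility on
IOP, and freezes R_t at its preoperative calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Optional

from scipy.optimize import brentq

from .units import (
    CLINICAL_RESISTANCE_TO_SI,
    ULMIN_TO_M3S,
    MMHG_TO_PA,
)

__all__ = [
    "ImplantSpec",
    "EyeParameters",
    "BlebState",
    "SurgicalOutcome",
    "HydraulicResistance",
    "net_baseline_outflow",
    "implant_resistance",
    "trabecular_resistance",
    "postoperative_iop",
    "implant_flow_rate",
    "implant_pressure_drop",
    "solve_with_bleb_resistance",
    "efficacy_percent",
    "reynolds_number",
    "conservation_oracle",
    "predict_outcome",
]


class HydraulicResistance(NamedTuple):
    """A hydraulic resistance reported in both SI and clinical units."""

    pa_s_per_m3: float
    mmhg_per_ulmin: float

    @classmethod
    def from_si(cls, r_si: float) -> "HydraulicResistance":
        return cls(r_si, r_si / CLINICAL_RESISTANCE_TO_SI)

    @classmethod
    def from_clinical(cls, r_clin: float) -> "HydraulicResistance":
        return cls(r_clin * CLINICAL_RESISTANCE_TO_SI, r_clin)


@dataclass(frozen=True)
class ImplantSpec:
    """Geometry of a glaucoma drainage tube.

    Parameters
    ----------
    name:
        Device label.
    lumen_diameter_um:
        Hydraulic diameter Dh of the lumen, µm.
    length_mm:
        Total tube length Lv, mm.
    shape_factor:
        Dimensionless cross-section constant L of the generalized
        Hagen–Poiseuille law; 1 for a circular lumen.
    wall_thickness_um, ac_protrusion_mm, iris_clearance_um:
        Informational metadata (tube wall, length protruding into the
        anterior chamber d_0, clearance above the iris l_0).  They never
        enter any hydraulic computation: position-independence of the
        outcome is a prediction of the lumped model, not an omission.
    """

    name: str
    lumen_diameter_um: float
    length_mm: float
    shape_factor: float = 1.0
    wall_thickness_um: Optional[float] = None
    ac_protrusion_mm: Optional[float] = None
    iris_clearance_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lumen_diameter_um <= 0:
            raise ValueError(f"lumen diameter must be positive, got {self.lumen_diameter_um}")
        if self.length_mm < 0:
            raise ValueError(f"tube length must be non-negative, got {self.length_mm}")
        if self.shape_factor <= 0:
            raise ValueError(f"shape factor must be positive, got {self.shape_factor}")


@dataclass(frozen=True)
class EyeParameters:
    """Preoperative pressures, inflow and fluid properties of the eye.

    Pressures in mmHg, flows in µl/min, viscosity in Pa·s, density in kg/m³.
    ``p_g`` is the preoperative (baseline) IOP; ``p_ev`` the pressure at the
    exit of Schlemm's canal (episcleral venous pressure); ``Q_cb`` the
    ciliary inflow, of which ``uveoscleral_fraction`` leaves through the
    pressure-independent uveoscleral route.
    """

    p_g: float
    p_ev: float = 10.5
    Q_cb: float = 2.0
    uveoscleral_fraction: float = 0.15
    viscosity: float = 7e-4
    density: float = 998.2

    def __post_init__(self) -> None:
        if self.p_ev < 0:
            raise ValueError("p_ev must be non-negative")
        if self.p_g <= self.p_ev:
            raise ValueError(f"p_g ({self.p_g}) must exceed p_ev ({self.p_ev})")
        if self.Q_cb <= 0:
            raise ValueError("ciliary inflow must be positive")
        if not 0.0 <= self.uveoscleral_fraction < 1.0:
            raise ValueError("uveoscleral fraction must lie in [0, 1)")
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def Q_0(self) -> float:
        """Net baseline outflow through the trabecular route, µl/min."""
        return net_baseline_outflow(self.Q_cb, self.uveoscleral_fraction)


@dataclass(frozen=True)
class BlebState:
    """Filtration-bleb description: imposed pressure or hydraulic resistance.

    ``fixed_pressure`` mode imposes the bleb pressure p_b directly (mmHg);
    ``resistance`` mode describes the subconjunctival tissue by a
    resistance R_b (mmHg per µl/min) draining toward a reference pressure
    p_r (≈ 0 in the estimates of the bleb-absorption literature).
    """

    mode: Literal["fixed_pressure", "resistance"]
    p_b: Optional[float] = None
    R_b: Optional[float] = None
    p_r: float = 0.0

    def __post_init__(self) -> None:
        if self.mode == "fixed_pressure":
            if self.p_b is None or self.p_b < 0:
                raise ValueError("fixed_pressure mode requires p_b >= 0")
        elif self.mode == "resistance":
            if self.R_b is None or self.R_b < 0:
                raise ValueError("resistance mode requires R_b >= 0")
            if self.p_r < 0:
                raise ValueError("reference pressure must be non-negative")
        else:
            raise ValueError(f"unknown bleb mode {self.mode!r}")

    @classmethod
    def fixed(cls, p_b: float) -> "BlebState":
        return cls(mode="fixed_pressure", p_b=p_b)

    @classmethod
    def resistive(cls, R_b: float, p_r: float = 0.0) -> "BlebState":
        return cls(mode="resistance", R_b=R_b, p_r=p_r)


@dataclass(frozen=True)
class SurgicalOutcome:
    """Predicted steady state after implantation.

    All pressures in mmHg, flows in µl/min.  ``p_b_effective`` is the bleb
    pressure actually realized (the imposed p_b, or the solved pressure in
    resistance mode).  ``efficacy`` is the percent IOP reduction relative
    to baseline; negative when scarring drives p_c above p_g.
    """

    p_c: float
    p_b_effective: float
    Q_v: float
    Q_trab: float
    delta_p_implant: float
    efficacy: float
    reynolds: float

    def as_dict(self) -> dict:
        return {
            "pc_mmHg": self.p_c,
            "pb_mmHg": self.p_b_effective,
            "qv_ul_min": self.Q_v,
            "q_trab_ul_min": self.Q_trab,
            "delta_p_implant_mmHg": self.delta_p_implant,
            "efficacy_pct": self.efficacy,
            "reynolds": self.reynolds,
        }


def net_baseline_outflow(Q_cb: float, uveoscleral_fraction: float) -> float:
    """Net flow Q_0 = Q_cb·(1 − f) evacuated by the trabecular route, µl/min."""
    if Q_cb <= 0:
        raise ValueError("ciliary inflow must be positive")
    if not 0.0 <= uveoscleral_fraction < 1.0:
        raise ValueError("uveoscleral fraction must lie in [0, 1)")
    return Q_cb * (1.0 - uveoscleral_fraction)


def implant_resistance(implant: ImplantSpec, viscosity: float) -> HydraulicResistance:
    """Hagen–Poiseuille resistance R_v = 128·L·Lv·µ/(π·Dh⁴) of the tube."""
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    dh = implant.lumen_diameter_um * 1e-6
    lv = implant.length_mm * 1e-3
    r_si = 128.0 * implant.shape_factor * lv * viscosity / (math.pi * dh**4)
    return HydraulicResistance.from_si(r_si)


def trabecular_resistance(p_g: float, p_ev: float, Q_0: float) -> HydraulicResistance:
    """Lumped trabecular/Schlemm resistance calibrated from the preoperative state.

    R_t = (p_g − p_ev)/Q_0, held constant after surgery.
    """
    if p_g <= p_ev:
        raise ValueError("calibration requires p_g > p_ev")
    if Q_0 <= 0:
        raise ValueError("baseline outflow must be positive")
    return HydraulicResistance.from_clinical((p_g - p_ev) / Q_0)


def _implant_head_mmhg(implant: ImplantSpec, eye: EyeParameters) -> float:
    """Pressure head a = Q_0·R_v in mmHg; the tube's share of the network."""
    r_v = implant_resistance(implant, eye.viscosity)
    return eye.Q_0 * r_v.mmhg_per_ulmin


def postoperative_iop(implant: ImplantSpec, eye: EyeParameters, p_b: float) -> float:
    """Postoperative IOP p_c of the two-path network at bleb pressure p_b.

    Flow conservation (p_c − p_ev)/R_t + (p_c − p_b)/R_v = Q_0 gives

        p_c = (a·p_g + p_b·(p_g − p_ev)) / (a + p_g − p_ev),  a = Q_0·R_v,

    a convex combination of p_g and p_b: tighter tubes (large a) leave the
    IOP near baseline, wide tubes pull it toward the bleb pressure.
    """
    a = _implant_head_mmhg(implant, eye)
    return (a * eye.p_g + p_b * (eye.p_g - eye.p_ev)) / (a + eye.p_g - eye.p_ev)


def implant_flow_rate(implant: ImplantSpec, eye: EyeParameters, p_b: float) -> float:
    """Flow Q_v through the tube, µl/min; negative when p_b > p_g (reverse flow)."""
    a = _implant_head_mmhg(implant, eye)
    return eye.Q_0 * (eye.p_g - p_b) / (a + eye.p_g - eye.p_ev)


def implant_pressure_drop(implant: ImplantSpec, eye: EyeParameters, p_b: float) -> float:
    """Pressure drop p_c − p_b across the tube, mmHg (closed form)."""
    a = _implant_head_mmhg(implant, eye)
    return a * (eye.p_g - p_b) / (a + eye.p_g - eye.p_ev)


def efficacy_percent(p_g: float, p_c: float) -> float:
    """Hypotensive efficacy 100·(p_g − p_c)/p_g; negative if p_c exceeds baseline."""
    if p_g <= 0:
        raise ValueError("baseline IOP must be positive")
    return 100.0 * (p_g - p_c) / p_g


def reynolds_number(Q_v: float, implant: ImplantSpec, eye: EyeParameters) -> float:
    """Reynolds number Re = ρ·U·Dh/µ of the tube flow, U = Q_v/(π·Dh²/4)."""
    dh = implant.lumen_diameter_um * 1e-6
    q_si = abs(Q_v) * ULMIN_TO_M3S
    u = q_si / (math.pi * dh**2 / 4.0)
    return eye.density * u * dh / eye.viscosity


def _outcome_from_pc(
    implant: ImplantSpec, eye: EyeParameters, p_c: float, p_b: float
) -> SurgicalOutcome:
    r_t = trabecular_resistance(eye.p_g, eye.p_ev, eye.Q_0).mmhg_per_ulmin
    r_v = implant_resistance(implant, eye.viscosity).mmhg_per_ulmin
    q_trab = (p_c - eye.p_ev) / r_t
    q_v = (p_c - p_b) / r_v if r_v > 0 else eye.Q_0 - q_trab
    return SurgicalOutcome(
        p_c=p_c,
        p_b_effective=p_b,
        Q_v=q_v,
        Q_trab=q_trab,
        delta_p_implant=p_c - p_b,
        efficacy=efficacy_percent(eye.p_g, p_c),
        reynolds=reynolds_number(q_v, implant, eye),
    )


def predict_outcome(
    implant: ImplantSpec, eye: EyeParameters, bleb: BlebState
) -> SurgicalOutcome:
    """Full postoperative steady state for either bleb description."""
    if bleb.mode == "fixed_pressure":
        p_c = postoperative_iop(implant, eye, bleb.p_b)
        return _outcome_from_pc(implant, eye, p_c, bleb.p_b)
    return solve_with_bleb_resistance(implant, eye, bleb)


def solve_with_bleb_resistance(
    implant: ImplantSpec, eye: EyeParameters, bleb: BlebState
) -> SurgicalOutcome:
    """Exact solve of the three-resistor chain: trabecular ∥ (tube → bleb → tissue).

    Unknowns (p_c, p_b, Q_v) satisfy flow conservation, the tube's
    Hagen–Poiseuille law, and the bleb absorption law p_b − p_r = R_b·Q_v.
    Eliminating pressures gives Q_v = (Q_0·R_t + p_ev − p_r)/(R_t + R_v + R_b).
    """
    if bleb.mode != "resistance":
        raise ValueError("solve_with_bleb_resistance requires a resistance-mode bleb")
    r_t = trabecular_resistance(eye.p_g, eye.p_ev, eye.Q_0).mmhg_per_ulmin
    r_v = implant_resistance(implant, eye.viscosity).mmhg_per_ulmin
    q_v = (eye.Q_0 * r_t + eye.p_ev - bleb.p_r) / (r_t + r_v + bleb.R_b)
    p_b = bleb.p_r + bleb.R_b * q_v
    p_c = p_b + r_v * q_v
    return SurgicalOutcome(
        p_c=p_c,
        p_b_effective=p_b,
        Q_v=q_v,
        Q_trab=(p_c - eye.p_ev) / r_t,
        delta_p_implant=p_c - p_b,
        efficacy=efficacy_percent(eye.p_g, p_c),
        reynolds=reynolds_number(q_v, implant, eye),
    )


def conservation_oracle(
    implant: ImplantSpec, eye: EyeParameters, p_b: float
) -> SurgicalOutcome:
    """Independent numerical solve of the outflow network (validation path).

    Root-finds the anterior-chamber pressure p_c at which the two outflow
    paths together carry exactly Q_0, without using the closed-form
    expression.  Intended for cross-checking the analytic formulas.
    """
    r_t = trabecular_resistance(eye.p_g, eye.p_ev, eye.Q_0).mmhg_per_ulmin
    r_v = implant_resistance(implant, eye.viscosity).mmhg_per_ulmin

    def residual(p_c: float) -> float:
        return (p_c - eye.p_ev) / r_t + (p_c - p_b) / r_v - eye.Q_0

    lo = min(p_b, eye.p_ev) - 1.0
    hi = max(eye.p_g, p_b) + 1.0
    assert residual(lo) < 0 < residual(hi), "root not bracketed for admissible inputs"
    p_c = brentq(residual, lo, hi, xtol=1e-13, rtol=1e-15)
    return _outcome_from_pc(implant, eye, p_c, p_b)
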