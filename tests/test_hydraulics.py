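"""Unit and property tests of the two-path outflow network."""

import math
from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from migsflow import (
    BlebState,
    EyeParameters,
    ImplantSpec,
    conservation_oracle,
    efficacy_percent,
    implant_flow_rate,
    implant_pressure_drop,
    implant_resistance,
    net_baseline_outflow,
    postoperative_iop,
    predict_outcome,
    reynolds_number,
    solve_with_bleb_resistance,
    trabecular_resistance,
)


@pytest.mark.parametrize(
    "q_cb, frac, expected",
    [(2.0, 0.15, 1.7), (2.0, 0.0, 2.0), (3.0, 0.5, 1.5)],
)
def test_net_baseline_outflow(q_cb, frac, expected):
    assert net_baseline_outflow(q_cb, frac) == pytest.approx(expected)


@pytest.mark.parametrize("q_cb, frac", [(-1.0, 0.1), (0.0, 0.1), (2.0, 1.0), (2.0, -0.1)])
def test_net_baseline_outflow_rejects_bad_inputs(q_cb, frac):
    with pytest.raises(ValueError):
        net_baseline_outflow(q_cb, frac)


class TestImplantResistance:
    def test_xen45_reference_value(self, xen45):
        # frozen from direct Hagen-Poiseuille evaluation, cross-checked by
        # imposing 1 ul/min and reading the pressure drop
        r = implant_resistance(xen45, 7e-4)
        assert r.pa_s_per_m3 == pytest.approx(4.173e13, rel=1e-3)
        # pressure-drop oracle: R * Q for Q = 1 ul/min, in mmHg
        dp_mmhg = r.mmhg_per_ulmin * 1.0
        assert dp_mmhg == pytest.approx(5.217, rel=1e-3)

    def test_zero_length_tube(self, xen45):
        r = implant_resistance(replace(xen45, length_mm=0.0), 7e-4)
        assert r.pa_s_per_m3 == 0.0

    def test_diameter_fourth_power_ratio(self, xen45, xen63):
        same_length = replace(xen63, length_mm=xen45.length_mm)
        ratio = (
            implant_resistance(same_length, 7e-4).pa_s_per_m3
            / implant_resistance(xen45, 7e-4).pa_s_per_m3
        )
        assert ratio == pytest.approx((45.0 / 63.0) ** 4, rel=1e-12)

    def test_rejects_bad_inputs(self, xen45):
        with pytest.raises(ValueError):
            implant_resistance(xen45, -1.0)
        with pytest.raises(ValueError):
            ImplantSpec("bad", lumen_diameter_um=0.0, length_mm=6.0)


class TestTrabecularResistance:
    def test_reference_calibration(self):
        r = trabecular_resistance(25.0, 10.5, 1.7)
        assert r.mmhg_per_ulmin == pytest.approx(8.529, rel=1e-3)
        assert r.pa_s_per_m3 == pytest.approx(6.82e13, rel=1e-2)

    @pytest.mark.parametrize("x", [0.5, 5.0, 19.5])
    def test_definition_identity(self, x):
        r = trabecular_resistance(10.5 + x, 10.5, 1.7)
        assert r.mmhg_per_ulmin == pytest.approx(x / 1.7)

    def test_higher_baseline_raises_resistance(self):
        assert trabecular_resistance(30.0, 10.5, 1.7).mmhg_per_ulmin == pytest.approx(
            11.47, rel=1e-3
        )

    def test_uncalibratable(self):
        with pytest.raises(ValueError):
            trabecular_resistance(10.0, 10.5, 1.7)


class TestPostoperativeIOP:
    def test_reported_summary_values(self, xen45, xen63, preserflo):
        # integer-rounded postoperative IOPs at p_b = 10 mmHg
        cases = [
            (xen45, 30.0, 16), (xen45, 50.0, 17),
            (xen63, 30.0, 12), (xen63, 50.0, 12),
            (preserflo, 30.0, 12), (preserflo, 50.0, 12),
        ]
        for implant, p_g, expected in cases:
            p_c = postoperative_iop(implant, EyeParameters(p_g=p_g), 10.0)
            assert round(p_c) == expected

    def test_equal_pressures_are_a_fixed_point(self, xen63, eye30):
        assert postoperative_iop(xen63, eye30, 30.0) == pytest.approx(30.0)

    def test_diameter_limits(self, xen45, eye30):
        narrow = replace(xen45, lumen_diameter_um=1e-3)
        wide = replace(xen45, lumen_diameter_um=1e6)
        assert postoperative_iop(narrow, eye30, 10.0) == pytest.approx(30.0, abs=1e-6)
        assert postoperative_iop(wide, eye30, 10.0) == pytest.approx(10.0, abs=1e-6)

    @pytest.mark.parametrize("p_b", [0.0, 5.0, 17.0, 34.0])
    def test_monotone_increasing_in_bleb_pressure(self, xen63, eye30, p_b):
        assert postoperative_iop(xen63, eye30, p_b) < postoperative_iop(
            xen63, eye30, p_b + 1.0
        )

    def test_monotone_in_geometry(self, xen45, eye30):
        lengths = [2.0, 4.0, 6.0, 8.0, 12.0]
        pcs = [
            postoperative_iop(replace(xen45, length_mm=lv), eye30, 10.0)
            for lv in lengths
        ]
        assert pcs == sorted(pcs) and len(set(pcs)) == len(pcs)
        diameters = [30.0, 45.0, 63.0, 90.0, 150.0]
        pcs_d = [
            postoperative_iop(replace(xen45, lumen_diameter_um=dh), eye30, 10.0)
            for dh in diameters
        ]
        assert pcs_d == sorted(pcs_d, reverse=True)


class TestImplantFlow:
    def test_no_gradient_no_flow(self, xen63, eye30):
        assert implant_flow_rate(xen63, eye30, 30.0) == pytest.approx(0.0)

    def test_xen63_reference_flow(self, xen63):
        # frozen from the conservation-network root-find at p_b = 15 mmHg
        eye = EyeParameters(p_g=25.0)
        assert implant_flow_rate(xen63, eye, 15.0) == pytest.approx(1.0114, abs=5e-4)
        oracle = conservation_oracle(xen63, eye, 15.0)
        assert implant_flow_rate(xen63, eye, 15.0) == pytest.approx(
            oracle.Q_v, abs=1e-9
        )

    def test_reverse_flow_when_bleb_scars(self, xen63, eye30):
        assert implant_flow_rate(xen63, eye30, 34.0) < 0.0

    def test_pressure_drop_consistency(self, xen45, eye30):
        dp = implant_pressure_drop(xen45, eye30, 10.0)
        assert dp == pytest.approx(postoperative_iop(xen45, eye30, 10.0) - 10.0,
                                   abs=1e-9)
        assert dp == pytest.approx(6.25, abs=0.01)
        assert implant_pressure_drop(xen45, eye30, 30.0) == pytest.approx(0.0)


class TestBlebResistanceMode:
    def test_short_circuit_bleb(self, xen45, eye30):
        out = solve_with_bleb_resistance(xen45, eye30, BlebState.resistive(0.0))
        assert out.p_b_effective == pytest.approx(0.0)
        assert out.p_c == pytest.approx(postoperative_iop(xen45, eye30, 0.0), abs=1e-9)

    def test_blocked_bleb_recovers_baseline(self, xen45, eye30):
        out = solve_with_bleb_resistance(xen45, eye30, BlebState.resistive(1e12))
        assert out.Q_v == pytest.approx(0.0, abs=1e-9)
        assert out.p_c == pytest.approx(30.0, abs=1e-6)

    def test_round_trip_with_fixed_pressure_path(self, xen63):
        # choose R_b so the solved bleb pressure lands exactly at 15 mmHg
        eye = EyeParameters(p_g=25.0)
        r_t = trabecular_resistance(eye.p_g, eye.p_ev, eye.Q_0).mmhg_per_ulmin
        r_v = implant_resistance(xen63, eye.viscosity).mmhg_per_ulmin
        target_pb = 15.0
        r_b = target_pb * (r_t + r_v) / (eye.Q_0 * r_t + eye.p_ev - target_pb)
        out = solve_with_bleb_resistance(xen63, eye, BlebState.resistive(r_b))
        assert out.p_b_effective == pytest.approx(target_pb, abs=1e-9)
        assert out.Q_v == pytest.approx(
            implant_flow_rate(xen63, eye, target_pb), abs=1e-9
        )


class TestEfficacyAndReynolds:
    def test_efficacy_values(self):
        assert efficacy_percent(50.0, 12.0) == pytest.approx(76.0)
        assert efficacy_percent(18.0, 18.0) == 0.0
        assert efficacy_percent(25.0, 30.58) == pytest.approx(-22.32)
        with pytest.raises(ValueError):
            efficacy_percent(0.0, 12.0)

    def test_reynolds(self, xen45, eye30):
        assert reynolds_number(0.0, xen45, eye30) == 0.0
        assert reynolds_number(1.0, xen45, eye30) == pytest.approx(0.672, abs=1e-3)

    def test_laminar_over_study_grid(self, xen45, xen63, preserflo):
        for implant in (xen45, xen63, preserflo):
            for p_g in (25.0, 30.0, 50.0):
                eye = EyeParameters(p_g=p_g)
                for p_b in (0.0, 2.0, 5.0, 10.0, 17.0, 20.0, 34.0):
                    out = predict_outcome(implant, eye, BlebState.fixed(p_b))
                    assert out.reynolds < 10.0


admissible = st.fixed_dictionaries({
    "dh": st.floats(20.0, 200.0),
    "lv": st.floats(1.0, 15.0),
    "p_ev": st.floats(0.0, 20.0),
    "head": st.floats(0.5, 40.0),   # p_g - p_ev
    "p_b": st.floats(0.0, 60.0),
    "mu": st.floats(5e-4, 1.5e-3),
    "q_cb": st.floats(1.0, 3.0),
    "frac": st.floats(0.0, 0.5),
})


def _build(params):
    implant = ImplantSpec("rand", params["dh"], params["lv"])
    eye = EyeParameters(
        p_g=params["p_ev"] + params["head"], p_ev=params["p_ev"],
        Q_cb=params["q_cb"], uveoscleral_fraction=params["frac"],
        viscosity=params["mu"],
    )
    return implant, eye, params["p_b"]


@settings(max_examples=150, deadline=None, derandomize=True)
@given(admissible)
def test_closed_form_matches_conservation_oracle(params):
    """The analytic IOP/flow formulas agree with an independent root-find."""
    implant, eye, p_b = _build(params)
    oracle = conservation_oracle(implant, eye, p_b)
    assert postoperative_iop(implant, eye, p_b) == pytest.approx(
        oracle.p_c, abs=1e-9
    )
    assert implant_flow_rate(implant, eye, p_b) == pytest.approx(
        oracle.Q_v, abs=1e-9
    )
    assert implant_pressure_drop(implant, eye, p_b) == pytest.approx(
        oracle.p_c - p_b, abs=1e-9
    )


@settings(max_examples=150, deadline=None, derandomize=True)
@given(admissible)
def test_outcome_invariants(params):
    """Conservation, bounds, pressure-drop identity and scar reversal."""
    implant, eye, p_b = _build(params)
    out = predict_outcome(implant, eye, BlebState.fixed(p_b))
    assert out.Q_v + out.Q_trab == pytest.approx(eye.Q_0, abs=1e-9)
    assert out.delta_p_implant == pytest.approx(out.p_c - p_b, abs=1e-9)
    lo, hi = min(p_b, eye.p_g), max(p_b, eye.p_g)
    assert lo - 1e-9 <= out.p_c <= hi + 1e-9
    if p_b > eye.p_g:
        assert out.Q_v < 0 and out.p_c > eye.p_g
    elif p_b < eye.p_g:
        assert out.Q_v > 0 and p_b < out.p_c < eye.p_g


def test_position_metadata_never_enters_hydraulics(xen45, eye30):
    """Tube protrusion and iris clearance cannot change the outcome."""
    moved = replace(xen45, ac_protrusion_mm=3.0, iris_clearance_um=200.0)
    for p_b in (0.0, 10.0, 34.0):
        assert postoperative_iop(moved, eye30, p_b) == postoperative_iop(
            xen45, eye30, p_b
        )
        assert implant_flow_rate(moved, eye30, p_b) == implant_flow_rate(
            xen45, eye30, p_b
        )
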