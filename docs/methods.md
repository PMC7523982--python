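# Methods

## The outflow network

The postoperative eye is modelled as a steady hydraulic network. Aqueous
humor enters the anterior chamber at the net rate Q₀ = Q_cb·(1 − f), where
Q_cb is the ciliary inflow and f the fraction drained by the
pressure-independent uveoscleral route, and leaves through two parallel
resistances:

* **Trabecular path.** The meshwork and Schlemm's canal are lumped into a
  single linear resistance R_t = (p_g − p_ev)/Q₀, calibrated so that the
  preoperative IOP p_g and the Schlemm-exit (episcleral venous) pressure
  p_ev are recovered at the preoperative flow. R_t is frozen at this
  calibration after surgery — a deliberate simplification: real outflow
  facility varies with IOP and with remodelling of the meshwork.
* **Implant path.** The microshunt is a straight tube of hydraulic
  diameter Dh and length Lv carrying creeping flow (Re ≲ 1 at
  physiological rates), so its resistance is the generalized
  Hagen–Poiseuille value R_v = 128·L·Lv·µ/(π·Dh⁴), with L a dimensionless
  cross-section shape factor (1 for the circular lumens of all three
  built-in devices; exposed for non-circular designs). The tube discharges
  into the filtration bleb at pressure p_b.

Writing flow conservation at the chamber node,
(p_c − p_ev)/R_t + (p_c − p_b)/R_v = Q₀, and substituting the calibrated
R_t yields the closed form implemented in `hydraulics.postoperative_iop`:

    p_c = (a·p_g + p_b·(p_g − p_ev)) / (a + p_g − p_ev),    a = Q₀·R_v.

This is the dimensionally consistent flow-conservation solution of the
network; the implant flow Q_v = Q₀·(p_g − p_b)/(a + p_g − p_ev) and tube
pressure drop a·(p_g − p_b)/(a + p_g − p_ev) follow from it. The test
suite enforces agreement with `conservation_oracle`, an independent
root-finding solve of the conservation equation, to 10⁻⁹ mmHg over a
thousand random admissible scenarios, so any algebraic slip in one path
would be caught by the other.

Structural consequences of the linear network, all under test:

* min(p_b, p_g) ≤ p_c ≤ max(p_b, p_g); p_c is increasing in p_b and Lv and
  decreasing in Dh.
* Q_v + Q_trab = Q₀ exactly (steady-state conservation).
* p_b > p_g (a heavily scarred bleb) reverses the tube flow and raises the
  IOP *above* baseline — the model's account of late filtration failure.
* The tube's protrusion into the chamber (d₀) and clearance above the iris
  (l₀) are carried as metadata only and provably cannot change the
  outcome: position-independence is a prediction of the lumped model.

### Bleb descriptions

Two modes are supported. *Fixed pressure* imposes p_b directly; the
conventional scenario values are 2 mmHg (first postoperative day), 5 mmHg
(first week), 17 mmHg (mature bleb without scarring) and 34 mmHg (scarred
bleb). *Resistance* mode instead gives the subconjunctival tissue an
absorption law p_b − p_r = R_b·Q_v with reference pressure p_r ≈ 0; the
three-resistor chain (trabecular ∥ tube+bleb) is then solved exactly, and
the limits R_b → 0 (short-circuit bleb) and R_b → ∞ (fully blocked,
p_c → p_g, Q_v → 0) are verified in the tests.

### Parameter defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| Q_cb | 2.0 | µl/min | standard adult ciliary inflow |
| f (uveoscleral) | 0.15 | — | gives the net Q₀ = 1.7 µl/min trabecular flow |
| p_ev | 10.5 | mmHg | episcleral venous pressure |
| µ | 7×10⁻⁴ | Pa·s | aqueous viscosity at 37 °C; the room-temperature 10⁻³ Pa·s value is configurable but not the default |
| ρ₀ | 998.2 | kg/m³ | aqueous density |

All interfaces use clinical units (mmHg, µl/min, µm, mm); conversions are
fixed at 1 mmHg = 133.322 Pa and 1 µl/min = 1.6̅×10⁻¹¹ m³/s in
`units.py`. Note that 3D CFD studies of the same configuration often
impose the full 2.0 µl/min inflow at the chamber without subtracting the
uveoscleral share; both operating points are reachable through the eye
block of the config file.

### Rounding policies

Scenario tables report p_c to one decimal and efficacy to the nearest
percent. Summary efficacies can be computed from the exact p_c
(`efficacy_rounding="unrounded"`, the default) or from the
integer-rounded p_c (`"rounded"`); the latter is how a headline figure
like "12 mmHg (76 % reduction)" at a 50 mmHg baseline arises, since
100·(50 − 12)/50 = 76. Both policies are exposed because reported tables
in the literature mix them.

### The packaged reference grid

`migsflow.printed` carries a one-time transcription of a published
device × baseline × bleb-pressure IOP grid used for regression comparison
(`compare_to_printed`). Cells where the published 3D-simulation values
depart from the analytical model by more than 0.5 mmHg are annotated
`cfd_noise` — these 44 of 108 cells are concentrated at low bleb pressures
in the 25 and 50 mmHg baseline blocks, while the 30 mmHg block and every
17/34 mmHg bleb column agree to ≤0.15 mmHg. Regression tests target only
the concordant cells; the discordant ones are reported, never asserted.

## The convection cavity

### What it models, and what it does not

With the eyelid open and the body upright, the posterior cornea sits
≈3 °C below body temperature and buoyancy drives a recirculation of
aqueous humor. The solver reduces the domed 3D chamber to a 2D vertical
rectangular slot in the plane containing gravity and the cornea–iris gap:
cold wall (cornea, 34 °C) and hot wall (iris/lens, 37 °C) vertical and
separated by the chamber depth d = 3.2 mm, slot height equal to the
chamber diameter 12 mm, adiabatic end walls, gravity parallel to the
walls. This preserves the governing groups — Rayleigh number
Ra = gβΔT·d³ρ²Cp/(µk) ≈ 2.9×10³ (g = 9.81 m/s², β = 3×10⁻⁴ K⁻¹,
k = 0.6 W/m/K, Cp = 4182 J/kg/K) and Pr ≈ 4.9 — and therefore the
velocity, dynamic-pressure and shear *scales*, but not the exact 3D
wall-shear distribution, which depends on the domed corneal geometry and
the iris contour. The package therefore asserts order-of-magnitude bands
(e.g. wall shear 0.1–10 mPa, at least one order of magnitude below the
≈0.1 Pa endothelial-detachment threshold) rather than point values, and
makes no claim about per-position shear differences.

### Formulation and numerics

Stream-function–vorticity with the Boussinesq body force, nondimensional
with the gap d and the thermal-diffusion scales, marched to steady state:

* first-order upwind convection, second-order central diffusion;
* explicit pseudo-time steps chosen per equation from the local stability
  bound (the temperature and vorticity equations advance with different
  steps — only the steady state is of interest, not the transient);
* two red–black SOR sweeps of the ψ-Poisson equation per step, with a
  final polish at convergence;
* Thom's wall-vorticity formula, including the along-wall ψ curvature
  term on boundary segments that carry through-flow;
* convergence when the residuals max|∂θ/∂t| and max|∂ω/∂t|/max|ω| fall
  below 10⁻⁸ (relative, nondimensional), default cap 10⁵ iterations;
  non-convergence raises an error carrying the residual history;
* temperature is advanced with a monotone scheme, so the discrete maximum
  principle (34 °C ≤ T ≤ 37 °C) holds exactly, and continuity is
  satisfied to round-off because velocities derive from ψ.

The default 128×64 grid resolves the gap with 64 nodes; a grid-refinement
check across 32×16 → 64×32 → 128×64 shows the peak velocity changing by
0.2 % and then 0.1 % between successive levels. At these resolutions the
solve takes seconds to a few tens of seconds on one core, which is why the
finest default level is 128×64; the refinement report exposes the
discretization error explicitly.

### Filtration through-flow and scale separation

The ciliary filtration (default 2 µl/min) enters through a pupil segment
of the hot wall and leaves through segments of the end walls adjacent to
the cold corners — the 2D proxy for the iridocorneal angle — imposed via
boundary stream-function values. This makes the superposition argument
directly testable: adding the through-flow changes the convective velocity
field by ≈0.1 % in L². The filtration speed scale is computed as
Q/(2π·(W/4)·d), the flow crossing the mid-chamber annular section of the
real (axisymmetric) chamber, giving ≈5×10⁻⁴ mm/s against a convective
peak of ≈0.9 mm/s, and the convective dynamic pressure ½ρ|u|² peaks near
3×10⁻⁶ mmHg against IOPs of tens of mmHg: the two flows are separated by
three orders of magnitude in velocity and seven in pressure, so neither
perturbs the other.

### Known limitations

* The lumped outflow model holds inflow and both outflow facilities
  constant; diurnal inflow variation (±30 %) and IOP-dependent facility
  are not represented.
* Bleb pressure is an input, not a prediction: the scarring trajectory
  must be supplied (or summarized through R_b).
* The 2D slot cannot reproduce per-position 3D wall-shear values, tube
  jets, or blinking/eyelid transients, and the pupil/angle source
  placement is a geometric simplification.
* First-order upwinding adds numerical diffusion; at Ra ~ 3×10³ the flow
  is smooth and the refinement study bounds the resulting error on the
  reported summaries to ≲1 %.
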