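"""Natural convection of aqueous humor in the anterior chamber (2D).

With the eyelid open and the body upright, the posterior cornea sits a few
degrees below body temperature and buoyancy drives a slow recirculation of
aqueous humor in the anterior chamber.  This module characterizes that flow
regime — velocity scale, dynamic pressure, wall shear stress — with a
steady 2D Boussinesq solver, and quantifies its separation from the much
weaker pressure-driven filtration flow.

Geometry
--------
The domed 3D chamber is reduced to a vertical rectangular slot in the plane
containing gravity and the cornea–iris gap: the cold wall (cornea, 34 °C)
and hot wall (iris/lens, 37 °C) are vertical and separated by the chamber
depth (3.2 mm); the slot height is the chamber diameter (12 mm); the end
walls are adiabatic.  This preserves the Rayleigh number and therefore the
scale analysis, but not the exact 3D wall-shear values, which is why the
package reports order-of-magnitude bands rather than point values.

Formulation
-----------
Stream-function–vorticity on a uniform grid, nondimensionalized with the
gap width d and the thermal diffusion scales (velocity α/d):

    ∂θ/∂t + u·∇θ = ∇²θ
    ∂ω/∂t + u·∇ω = Pr ∇²ω + Ra·Pr·∂θ/∂x
    ∇²ψ = −ω,   u = ∂ψ/∂z,  w = −∂ψ/∂x

marched to steady state with per-equation pseudo-time steps (first-order
upwind convection, Thom wall vorticity).  The optional ciliary filtration
inflow enters through a pupil segment of the hot wall and leaves at the
iridocorneal angles, imposed via boundary stream-function values, so the
superposition of the two flows can be tested directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .units import ULMIN_TO_M3S, pa_to_mmhg

__all__ = [
    "FluidProperties",
    "CavityProblem",
    "ConvectionSolution",
    "ConvergenceError",
    "rayleigh_number",
    "solve_cavity",
    "wall_shear_summary",
    "grid_refinement_check",
    "scale_separation_report",
]


@dataclass(frozen=True)
class FluidProperties:
    """Thermophysical properties of aqueous humor (37 °C unless noted)."""

    density: float = 998.2            # kg/m3
    expansion_coeff: float = 3e-4     # 1/K
    viscosity: float = 7e-4           # Pa.s
    conductivity: float = 0.6         # W/m/K
    specific_heat: float = 4182.0     # J/kg/K
    gravity: float = 9.81             # m/s2; sign selects orientation

    def __post_init__(self) -> None:
        for name in ("density", "expansion_coeff", "viscosity",
                     "conductivity", "specific_heat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def thermal_diffusivity(self) -> float:
        return self.conductivity / (self.density * self.specific_heat)

    @property
    def prandtl(self) -> float:
        return self.viscosity * self.specific_heat / self.conductivity


@dataclass(frozen=True)
class CavityProblem:
    """A differentially heated anterior-chamber cross-section.

    ``width`` is the chamber diameter (slot height, m), ``depth`` the
    cornea–iris gap (m).  ``grid`` is (nodes along width, nodes across
    depth).  ``inflow_ul_min`` is the ciliary filtration rate fed through
    the pupil segment; set 0 for pure convection.
    """

    width: float = 12e-3
    depth: float = 3.2e-3
    T_cornea: float = 34.0
    T_body: float = 37.0
    fluid: FluidProperties = field(default_factory=FluidProperties)
    grid: Tuple[int, int] = (128, 64)
    inflow_ul_min: float = 2.0
    tol: float = 1e-8
    max_iter: int = 100_000

    def __post_init__(self) -> None:
        if self.width <= 0 or self.depth <= 0:
            raise ValueError("cavity dimensions must be positive")
        if self.T_body < self.T_cornea:
            raise ValueError("body temperature must be >= corneal temperature")
        if self.grid[0] < 32 or self.grid[1] < 16:
            raise ValueError("grid must be at least 32x16")
        if self.inflow_ul_min < 0:
            raise ValueError("inflow must be non-negative")

    @property
    def delta_T(self) -> float:
        return self.T_body - self.T_cornea

    @property
    def aspect(self) -> float:
        return self.width / self.depth


class ConvergenceError(RuntimeError):
    """Raised when the pseudo-time march fails to reach steady state."""

    def __init__(self, message: str, residual_history: List[float]):
        super().__init__(message)
        self.residual_history = residual_history


def rayleigh_number(problem: CavityProblem) -> float:
    """Ra = g·β·ΔT·d³·ρ²·Cp/(µ·k) with d the cornea–iris gap."""
    f = problem.fluid
    return (
        abs(f.gravity) * f.expansion_coeff * problem.delta_T * problem.depth**3
        * f.density**2 * f.specific_heat / (f.viscosity * f.conductivity)
    )


@dataclass
class ConvectionSolution:
    """Converged steady fields (SI units) and derived wall/scale summaries."""

    problem: CavityProblem
    x: np.ndarray                 # cross-gap coordinate, m, shape (nx,)
    z: np.ndarray                 # vertical coordinate, m, shape (nz,)
    u: np.ndarray                 # cross-gap velocity, m/s, shape (nz, nx)
    w: np.ndarray                 # vertical velocity, m/s, shape (nz, nx)
    T: np.ndarray                 # temperature, degC, shape (nz, nx)
    dynamic_pressure: np.ndarray  # 0.5*rho*|u|^2, Pa, shape (nz, nx)
    psi: np.ndarray               # stream function, m2/s
    tau_cornea_mpa: np.ndarray    # wall shear profile on the cold wall, mPa
    tau_iris_mpa: np.ndarray      # wall shear profile on the hot wall, mPa
    residual_history: List[float]
    iterations: int

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.w)

    @property
    def u_max_mm_s(self) -> float:
        return float(self.speed.max()) * 1e3

    @property
    def u_mean_mm_s(self) -> float:
        return float(self.speed.mean()) * 1e3

    @property
    def q_dyn_max_pa(self) -> float:
        return float(self.dynamic_pressure.max())

    @property
    def q_dyn_max_mmhg(self) -> float:
        return pa_to_mmhg(self.q_dyn_max_pa)

    def summaries(self) -> Dict[str, float]:
        shear = wall_shear_summary(self)
        return {
            "u_max_mm_s": self.u_max_mm_s,
            "u_mean_mm_s": self.u_mean_mm_s,
            "q_dyn_max_pa": self.q_dyn_max_pa,
            "q_dyn_max_mmhg": self.q_dyn_max_mmhg,
            "tau_mean_mpa_cornea": shear["cornea"]["tau_mean_mpa"],
            "tau_max_mpa_cornea": shear["cornea"]["tau_max_mpa"],
            "tau_mean_mpa_iris": shear["iris"]["tau_mean_mpa"],
            "tau_max_mpa_iris": shear["iris"]["tau_max_mpa"],
            "rayleigh": rayleigh_number(self.problem),
        }


def _boundary_psi(problem: CavityProblem, z: np.ndarray, x: np.ndarray) -> Dict[str, np.ndarray]:
    """Boundary stream-function values imposing the filtration through-flow.

    The net nondimensional flux F enters across a pupil segment centred on
    the hot wall and leaves in equal halves through segments of the two end
    walls adjacent to the cold corner (the iridocorneal angles).  Walls are
    streamlines away from those segments; the cold wall carries psi = 0.
    """
    alpha = problem.fluid.thermal_diffusivity
    # 2D slice flux per unit out-of-plane width, nondimensionalized by alpha
    F = problem.inflow_ul_min * ULMIN_TO_M3S / problem.width / alpha
    A = problem.aspect
    nz, nx = z.size, x.size
    hot = np.full(nz, -F / 2.0)
    z1, z2 = 0.375 * A, 0.625 * A     # pupil segment, central quarter
    ramp = (z >= z1) & (z <= z2)
    hot[ramp] = -F / 2.0 + F * (z[ramp] - z1) / (z2 - z1)
    hot[z > z2] = F / 2.0
    cold = np.zeros(nz)
    x_out = 0.75                      # outlet segments hug the cold corner
    top = np.full(nx, F / 2.0)
    seg = x >= x_out
    top[seg] = F / 2.0 * (1.0 - x[seg]) / (1.0 - x_out)
    bottom = np.full(nx, -F / 2.0)
    bottom[seg] = -F / 2.0 * (1.0 - x[seg]) / (1.0 - x_out)
    return {"hot": hot, "cold": cold, "top": top, "bottom": bottom}


def solve_cavity(problem: CavityProblem) -> ConvectionSolution:
    """March the Boussinesq system to steady state.

    Deterministic for a fixed grid and tolerance.  Raises
    :class:`ConvergenceError` (carrying the residual history) if the
    relative residual does not fall below ``problem.tol`` within
    ``problem.max_iter`` iterations.
    """
    nz, nx = problem.grid[0], problem.grid[1]
    A = problem.aspect
    Pr = problem.fluid.prandtl
    Ra = rayleigh_number(problem)
    buoy_sign = math.copysign(1.0, problem.fluid.gravity)

    xs = np.linspace(0.0, 1.0, nx)
    zs = np.linspace(0.0, A, nz)
    dx = xs[1] - xs[0]
    dz = zs[1] - zs[0]

    theta = np.tile(0.5 - xs, (nz, 1))          # conduction profile start
    omega = np.zeros((nz, nx))
    psi = np.zeros((nz, nx))
    bpsi = _boundary_psi(problem, zs, xs)
    psi[:, 0] = bpsi["hot"]
    psi[:, -1] = bpsi["cold"]
    psi[0, :] = bpsi["bottom"]
    psi[-1, :] = bpsi["top"]

    # second derivative of psi along each wall (nonzero only on the
    # inlet/outlet ramps); enters the Thom wall-vorticity formula
    def _wall_tt(vals: np.ndarray, h: float) -> np.ndarray:
        out = np.zeros_like(vals)
        out[1:-1] = (vals[2:] - 2 * vals[1:-1] + vals[:-2]) / h**2
        return out

    hot_tt = _wall_tt(bpsi["hot"], dz)
    cold_tt = _wall_tt(bpsi["cold"], dz)
    top_tt = _wall_tt(bpsi["top"], dx)
    bottom_tt = _wall_tt(bpsi["bottom"], dx)

    u = np.zeros((nz, nx))
    w = np.zeros((nz, nx))

    # SOR factor for the Poisson solve (optimal-ish for this grid)
    sor = 2.0 / (1.0 + math.sin(math.pi / max(nz, nx)))
    inv_lap = 1.0 / (2.0 / dx**2 + 2.0 / dz**2)
    red_int = (np.add.outer(np.arange(nz), np.arange(nx)) % 2 == 0)[1:-1, 1:-1]

    def poisson_sweeps(n_sweeps: int) -> None:
        interior = psi[1:-1, 1:-1]  # view: masked updates write through
        for _ in range(n_sweeps):
            for mask in (red_int, ~red_int):
                lap = (
                    (psi[1:-1, 2:] + psi[1:-1, :-2]) / dx**2
                    + (psi[2:, 1:-1] + psi[:-2, 1:-1]) / dz**2
                )
                gs = inv_lap * (lap + omega[1:-1, 1:-1])
                interior[mask] += sor * (gs[mask] - interior[mask])

    def upwind_advect(f: np.ndarray) -> np.ndarray:
        """u·∇f with first-order upwinding, interior nodes."""
        fx_m = (f[1:-1, 1:-1] - f[1:-1, :-2]) / dx
        fx_p = (f[1:-1, 2:] - f[1:-1, 1:-1]) / dx
        fz_m = (f[1:-1, 1:-1] - f[:-2, 1:-1]) / dz
        fz_p = (f[2:, 1:-1] - f[1:-1, 1:-1]) / dz
        uu = u[1:-1, 1:-1]
        ww = w[1:-1, 1:-1]
        return (
            np.where(uu > 0, uu * fx_m, uu * fx_p)
            + np.where(ww > 0, ww * fz_m, ww * fz_p)
        )

    def laplacian(f: np.ndarray) -> np.ndarray:
        return (
            (f[1:-1, 2:] - 2 * f[1:-1, 1:-1] + f[1:-1, :-2]) / dx**2
            + (f[2:, 1:-1] - 2 * f[1:-1, 1:-1] + f[:-2, 1:-1]) / dz**2
        )

    diff_denom = 2.0 / dx**2 + 2.0 / dz**2
    residual_history: List[float] = []
    check_every = 200
    converged = False
    it = 0
    res = math.inf

    if problem.delta_T == 0.0 and problem.inflow_ul_min == 0.0:
        # no forcing at all: the rest state is the exact solution
        converged = True

    while not converged and it < problem.max_iter:
        poisson_sweeps(2)
        u[1:-1, 1:-1] = (psi[2:, 1:-1] - psi[:-2, 1:-1]) / (2 * dz)
        w[1:-1, 1:-1] = -(psi[1:-1, 2:] - psi[1:-1, :-2]) / (2 * dx)

        # Thom wall vorticity (with along-wall psi curvature at the ramps)
        omega[:, 0] = -2.0 * (psi[:, 1] - psi[:, 0]) / dx**2 - hot_tt
        omega[:, -1] = -2.0 * (psi[:, -2] - psi[:, -1]) / dx**2 - cold_tt
        omega[0, :] = -2.0 * (psi[1, :] - psi[0, :]) / dz**2 - bottom_tt
        omega[-1, :] = -2.0 * (psi[-2, :] - psi[-1, :]) / dz**2 - top_tt

        umax = float(np.abs(u).max())
        wmax = float(np.abs(w).max())
        adv = umax / dx + wmax / dz
        dt_theta = 0.8 / (diff_denom + adv)
        dt_omega = 0.8 / (Pr * diff_denom + adv)

        theta_x = (theta[1:-1, 2:] - theta[1:-1, :-2]) / (2 * dx)
        d_omega = (
            Pr * laplacian(omega) - upwind_advect(omega)
            + buoy_sign * Ra * Pr * theta_x
        )
        d_theta = laplacian(theta) - upwind_advect(theta)
        omega[1:-1, 1:-1] += dt_omega * d_omega
        theta[1:-1, 1:-1] += dt_theta * d_theta
        # adiabatic end walls
        theta[0, :] = theta[1, :]
        theta[-1, :] = theta[-2, :]
        theta[:, 0] = 0.5
        theta[:, -1] = -0.5

        it += 1
        if it % check_every == 0 or it == problem.max_iter:
            omega_scale = max(float(np.abs(omega).max()), 1.0)
            res_theta = float(np.abs(d_theta).max())       # |dθ/dt|, θ-scale 1
            res_omega = float(np.abs(d_omega).max()) / omega_scale
            res = max(res_theta, res_omega)
            residual_history.append(res)
            if res < problem.tol:
                converged = True

    if not converged:
        raise ConvergenceError(
            f"no steady state after {it} iterations (residual {res:.3e}, "
            f"tol {problem.tol:.1e})",
            residual_history,
        )
    poisson_sweeps(20)  # polish psi against the final vorticity
    u[1:-1, 1:-1] = (psi[2:, 1:-1] - psi[:-2, 1:-1]) / (2 * dz)
    w[1:-1, 1:-1] = -(psi[1:-1, 2:] - psi[1:-1, :-2]) / (2 * dx)

    f = problem.fluid
    alpha = f.thermal_diffusivity
    u_scale = alpha / problem.depth
    u_si = u * u_scale
    w_si = w * u_scale
    T = problem.T_cornea + (theta + 0.5) * problem.delta_T if problem.delta_T > 0 \
        else np.full_like(theta, problem.T_body)
    q_dyn = 0.5 * f.density * (u_si**2 + w_si**2)

    # wall shear from the tangential (vertical) velocity, second-order
    # one-sided difference at the two vertical walls, in mPa
    dxd = dx * problem.depth
    tau_iris = f.viscosity * (
        (-3 * w_si[:, 0] + 4 * w_si[:, 1] - w_si[:, 2]) / (2 * dxd)
    )
    tau_cornea = f.viscosity * (
        (3 * w_si[:, -1] - 4 * w_si[:, -2] + w_si[:, -3]) / (-2 * dxd)
    )
    return ConvectionSolution(
        problem=problem,
        x=xs * problem.depth,
        z=zs * problem.depth,
        u=u_si,
        w=w_si,
        T=T,
        dynamic_pressure=q_dyn,
        psi=psi * alpha,
        tau_cornea_mpa=np.abs(tau_cornea) * 1e3,
        tau_iris_mpa=np.abs(tau_iris) * 1e3,
        residual_history=residual_history,
        iterations=it,
    )


def wall_shear_summary(solution: ConvectionSolution) -> Dict[str, Dict[str, float]]:
    """Mean and maximum wall shear stress (mPa) on the cornea and iris walls."""
    out = {}
    for wall, tau in (("cornea", solution.tau_cornea_mpa),
                      ("iris", solution.tau_iris_mpa)):
        out[wall] = {
            "tau_mean_mpa": float(tau.mean()),
            "tau_max_mpa": float(tau.max()),
        }
    return out


def energy_balance(solution: ConvectionSolution) -> Dict[str, float]:
    """Integrated conductive heat flux through each vertical wall (W/m).

    At steady state with adiabatic end walls and no through-flow, the flux
    entering at the hot wall must match the flux leaving at the cold wall.
    """
    p = solution.problem
    k = p.fluid.conductivity
    dx = solution.x[1] - solution.x[0]
    T = solution.T
    dTdx_hot = (-3 * T[:, 0] + 4 * T[:, 1] - T[:, 2]) / (2 * dx)
    dTdx_cold = (3 * T[:, -1] - 4 * T[:, -2] + T[:, -3]) / (2 * dx)
    q_hot = -k * np.trapezoid(dTdx_hot, solution.z)
    q_cold = -k * np.trapezoid(dTdx_cold, solution.z)
    imbalance = abs(q_hot - q_cold) / max(abs(q_hot), 1e-300)
    return {"q_hot_w_per_m": float(q_hot), "q_cold_w_per_m": float(q_cold),
            "relative_imbalance": float(imbalance)}


def grid_refinement_check(
    problem: CavityProblem,
    levels: Sequence[Tuple[int, int]],
    pass_threshold: float = 0.01,
) -> Dict[str, object]:
    """Solve at successive resolutions and report the relative change of the
    velocity and wall-shear summaries between neighbouring levels."""
    if len(levels) < 2:
        raise ValueError("grid refinement needs at least two levels")
    from dataclasses import replace as _replace

    sols = [solve_cavity(_replace(problem, grid=tuple(lv))) for lv in levels]
    steps = []
    for coarse, fine in zip(sols, sols[1:]):
        du = abs(fine.u_max_mm_s - coarse.u_max_mm_s) / max(fine.u_max_mm_s, 1e-300)
        tc = wall_shear_summary(coarse)["cornea"]["tau_mean_mpa"]
        tf = wall_shear_summary(fine)["cornea"]["tau_mean_mpa"]
        dtau = abs(tf - tc) / max(abs(tf), 1e-300)
        steps.append({
            "levels": (tuple(coarse.problem.grid), tuple(fine.problem.grid)),
            "rel_change_u_max": du,
            "rel_change_tau_mean": dtau,
        })
    return {
        "steps": steps,
        "u_max_mm_s": [s.u_max_mm_s for s in sols],
        "passes": steps[-1]["rel_change_u_max"] < pass_threshold,
    }


def scale_separation_report(
    problem: CavityProblem,
    solution: Optional[ConvectionSolution] = None,
    iop_mmhg: float = 15.0,
) -> Dict[str, float]:
    """Quantify the two-flow superposition argument.

    The pressure-driven filtration flow crosses the mid-chamber annular
    section (circumference at half the chamber radius times the depth) at a
    speed orders of magnitude below the convective recirculation, and the
    convection's dynamic pressure is a vanishing fraction of the IOP, so
    neither flow perturbs the other.
    """
    if solution is None:
        solution = solve_cavity(problem)
    q_si = problem.inflow_ul_min * ULMIN_TO_M3S
    section = 2.0 * math.pi * (problem.width / 4.0) * problem.depth
    u_filt = q_si / section          # m/s
    u_max = solution.u_max_mm_s * 1e-3
    q_dyn_mmhg = solution.q_dyn_max_mmhg
    return {
        "u_filt_mm_s": u_filt * 1e3,
        "u_max_mm_s": solution.u_max_mm_s,
        "velocity_ratio": (u_filt * 1e3 / solution.u_max_mm_s)
        if solution.u_max_mm_s > 0 else 0.0,
        "q_dyn_max_mmhg": q_dyn_mmhg,
        "q_dyn_over_iop": q_dyn_mmhg / iop_mmhg,
        "separated": u_filt * 1e3 < 0.01 * solution.u_max_mm_s
        and q_dyn_mmhg < 1e-3 if solution.u_max_mm_s > 0 else True,
    }
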