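"""Four-population thymocyte homeostasis model.

State variables are the double-negative (DN), double-positive (DP) and
single-positive CD4/CD8 (SP4/SP8) thymocyte counts.  DN and DP cells occupy
the cortex, SP cells the medulla; each niche has a carrying capacity that
bounds precursor inflow, proliferation and the DP-to-SP transition through
logistic vacancy factors ``1 - x`` and ``1 - y`` with occupancies
``x = (T_DN + T_DP)/T_cort_max`` and ``y = (T_SP4 + T_SP8)/T_med_max``:

    dT_DN/dt  = phi*(1-x) - phi1*T_DN + lam1*(1-x)*T_DN - mu1*T_DN
    dT_DP/dt  = phi1*T_DN + lam2*(1-x)*T_DP
                - (phi4+phi8)*(1-y)*T_DP - mu2*T_DP
    dT_SP4/dt = phi4*(1-y)*T_DP - eps4*T_SP4 + lam4*(1-y)*T_SP4 - mu4*T_SP4
    dT_SP8/dt = phi8*(1-y)*T_DP - eps8*T_SP8 + lam8*(1-y)*T_SP8 - mu8*T_SP8

All rate constants are per day; time is measured in days internally and
ages in years (365 days/year by default).  Thymic output — the model's
functional readout — is the SP export rate ``eps4*T_SP4 + eps8*T_SP8``.

The quasi-steady state at fixed capacities is found semi-analytically: at a
fixed point every population is a rational function of the vacancy pair
(u, v) = (1-x, 1-y), which reduces the problem to two nested monotone
1-D root searches, followed by a damped Newton polish of the full 4-D
system.  The reduction vectorizes across large parameter batches, which is
what makes 150,000-set plausibility screens cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .involution import CarryingCapacities, InvolutionParams, capacities

__all__ = [
    "HomeostasisParams",
    "ThymocyteState",
    "SimulationSettings",
    "SteadyStateResult",
    "AgeSeries",
    "PARAM_NAMES",
    "CALIBRATION_INFANT_CAPACITIES",
    "rhs",
    "steady_state",
    "steady_state_batch",
    "simulate",
    "thymic_output",
]

#: Canonical parameter order used by array-based interfaces.
PARAM_NAMES = ("phi", "phi1", "mu1", "mu2", "lam1", "lam2", "phi4", "phi8",
               "lam4", "lam8", "mu4", "mu8", "eps4", "eps8")

#: Infant cortex/medulla capacities the homeostasis model was calibrated
#: against (fixed constants of the calibration; the involution sub-model's
#: `infant_capacities` reproduces them to within a few percent).
CALIBRATION_INFANT_CAPACITIES = CarryingCapacities(2.84e10, 1.05e10)


@dataclass(frozen=True)
class HomeostasisParams:
    """The fourteen rate constants of the homeostasis model.

    phi is the thymocyte precursor inflow (cells/day); phi1, phi4, phi8 are
    differentiation, lam* proliferation, mu* death and eps* egress rate
    constants (all per day).  Defaults are the calibrated baseline.
    """

    phi: float = 4.8e5
    phi1: float = 0.21
    mu1: float = 0.056
    mu2: float = 0.5
    lam1: float = 1.67
    lam2: float = 3.125
    phi4: float = 0.8
    phi8: float = 0.3
    lam4: float = 0.22
    lam8: float = 0.22
    mu4: float = 0.005
    mu8: float = 0.005
    eps4: float = 0.06
    eps8: float = 0.06

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"HomeostasisParams.{f.name} must be non-negative, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, nm) for nm in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "HomeostasisParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))


@dataclass(frozen=True)
class ThymocyteState:
    """Population sizes (cells) of the four modeled compartments."""

    t_dn: float
    t_dp: float
    t_sp4: float
    t_sp8: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"ThymocyteState.{f.name} must be non-negative and finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.t_dn, self.t_dp, self.t_sp4, self.t_sp8], dtype=float)

    @property
    def total(self) -> float:
        return self.t_dn + self.t_dp + self.t_sp4 + self.t_sp8


@dataclass(frozen=True)
class SimulationSettings:
    """Numerical plumbing: unit conversion, tolerances, grids."""

    days_per_year: float = 365.0
    abs_tol: float = 1.0
    rel_tol: float = 1e-8
    ss_tol: float = 1e-8
    max_time_days: float = 2.0e4
    output_step_years: float = 0.25
    output_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.days_per_year <= 0:
            raise ValueError("days_per_year must be positive")
        for nm in ("abs_tol", "rel_tol", "ss_tol", "max_time_days", "output_step_years"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")


@dataclass(frozen=True)
class SteadyStateResult:
    """Quasi-steady state with an honest convergence verdict.

    ``residual`` is the largest |net rate| relative to the gross production
    flux of the corresponding equation.
    """

    state: ThymocyteState | None
    converged: bool
    residual: float


def rhs(state: ThymocyteState | Sequence[float], caps: CarryingCapacities,
        p: HomeostasisParams) -> np.ndarray:
    """Net rates (cells/day) of the four populations.

    The equations are evaluated exactly as written: logistic vacancy
    factors are not clamped, so overcrowded states yield negative inflow
    and proliferation terms.
    """
    y = state.as_array() if isinstance(state, ThymocyteState) else np.asarray(state, dtype=float)
    if y.shape[-1] != 4 or not np.all(np.isfinite(y)):
        raise ValueError("state must be four finite population sizes")
    t_dn, t_dp, t_sp4, t_sp8 = y[..., 0], y[..., 1], y[..., 2], y[..., 3]
    u = 1.0 - (t_dn + t_dp) / caps.t_cort_max      # cortex vacancy
    v = 1.0 - (t_sp4 + t_sp8) / caps.t_med_max     # medulla vacancy
    f_dn = p.phi * u - p.phi1 * t_dn + p.lam1 * u * t_dn - p.mu1 * t_dn
    f_dp = (p.phi1 * t_dn + p.lam2 * u * t_dp
            - (p.phi4 + p.phi8) * v * t_dp - p.mu2 * t_dp)
    f_sp4 = p.phi4 * v * t_dp - p.eps4 * t_sp4 + p.lam4 * v * t_sp4 - p.mu4 * t_sp4
    f_sp8 = p.phi8 * v * t_dp - p.eps8 * t_sp8 + p.lam8 * v * t_sp8 - p.mu8 * t_sp8
    return np.stack([f_dn, f_dp, f_sp4, f_sp8], axis=-1)


def thymic_output(state: ThymocyteState, p: HomeostasisParams) -> float:
    """Rate of SP-cell export to the periphery, cells/day."""
    return p.eps4 * state.t_sp4 + p.eps8 * state.t_sp8


# --- vectorized steady-state core ----------------------------------------

def _pops_from_uv(u, v, P):
    """Populations as rational functions of the vacancy pair at a fixed point.

    Valid on the positive branch where every denominator is positive.
    """
    d1 = P["phi1"] + P["mu1"] - P["lam1"] * u
    t1 = P["phi"] * u / d1
    d2 = P["mu2"] + (P["phi4"] + P["phi8"]) * v - P["lam2"] * u
    t2 = P["phi1"] * t1 / d2
    d3 = P["eps4"] + P["mu4"] - P["lam4"] * v
    d4 = P["eps8"] + P["mu8"] - P["lam8"] * v
    t3 = P["phi4"] * v * t2 / d3
    t4 = P["phi8"] * v * t2 / d4
    return t1, t2, t3, t4


def _solve_uv(P, tc, tm, n_bisect: int = 60):
    """Nested bisection for the positive-branch fixed point.

    Inner problem: for fixed medulla vacancy v, the cortex residual
    g(u) = 1 - (T_DN + T_DP)/T_cort_max - u is strictly decreasing in u,
    positive at 0 and negative at the branch edge, so it has a unique root.
    The outer residual in v is bracketed the same way.
    """
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        u_prolif = np.where(P["lam1"] > 0, (P["phi1"] + P["mu1"]) / np.where(P["lam1"] > 0, P["lam1"], 1.0), np.inf)

        def u_of_v(v):
            u_dp = np.where(P["lam2"] > 0,
                            (P["mu2"] + (P["phi4"] + P["phi8"]) * v) / np.where(P["lam2"] > 0, P["lam2"], 1.0),
                            np.inf)
            hi = np.minimum(np.minimum(1.0, u_prolif), u_dp) * (1.0 - 1e-12)
            lo = np.zeros_like(hi)
            for _ in range(n_bisect):
                mid = 0.5 * (lo + hi)
                t1, t2, _, _ = _pops_from_uv(mid, v, P)
                g = 1.0 - (t1 + t2) / tc - mid
                up = g > 0
                lo = np.where(up, mid, lo)
                hi = np.where(up, hi, mid)
            return 0.5 * (lo + hi)

        v4 = np.where(P["lam4"] > 0, (P["eps4"] + P["mu4"]) / np.where(P["lam4"] > 0, P["lam4"], 1.0), np.inf)
        v8 = np.where(P["lam8"] > 0, (P["eps8"] + P["mu8"]) / np.where(P["lam8"] > 0, P["lam8"], 1.0), np.inf)
        hi = np.minimum(np.minimum(1.0, v4), v8) * (1.0 - 1e-12)
        lo = np.zeros_like(hi)
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            u = u_of_v(mid)
            t1, t2, t3, t4 = _pops_from_uv(u, mid, P)
            h = 1.0 - (t3 + t4) / tm - mid
            up = h > 0
            lo = np.where(up, mid, lo)
            hi = np.where(up, hi, mid)
        v = 0.5 * (lo + hi)
        u = u_of_v(v)
        pops = _pops_from_uv(u, v, P)
    return np.stack(pops, axis=-1)


def _rhs_arrays(Y, P, tc, tm):
    t1, t2, t3, t4 = Y[..., 0], Y[..., 1], Y[..., 2], Y[..., 3]
    u = 1.0 - (t1 + t2) / tc
    v = 1.0 - (t3 + t4) / tm
    f1 = P["phi"] * u - P["phi1"] * t1 + P["lam1"] * u * t1 - P["mu1"] * t1
    f2 = P["phi1"] * t1 + P["lam2"] * u * t2 - (P["phi4"] + P["phi8"]) * v * t2 - P["mu2"] * t2
    f3 = P["phi4"] * v * t2 - P["eps4"] * t3 + P["lam4"] * v * t3 - P["mu4"] * t3
    f4 = P["phi8"] * v * t2 - P["eps8"] * t4 + P["lam8"] * v * t4 - P["mu8"] * t4
    return np.stack([f1, f2, f3, f4], axis=-1)


def _gross_flux(Y, P, tc, tm):
    """Gross production flux per equation (positive terms only)."""
    t1, t2, t3, t4 = Y[..., 0], Y[..., 1], Y[..., 2], Y[..., 3]
    u = 1.0 - (t1 + t2) / tc
    v = 1.0 - (t3 + t4) / tm
    up = np.maximum(u, 0.0)
    vp = np.maximum(v, 0.0)
    g1 = P["phi"] * up + P["lam1"] * up * t1
    g2 = P["phi1"] * t1 + P["lam2"] * up * t2
    g3 = P["phi4"] * vp * t2 + P["lam4"] * vp * t3
    g4 = P["phi8"] * vp * t2 + P["lam8"] * vp * t4
    return np.stack([g1, g2, g3, g4], axis=-1)


def _jacobian(Y, P, tc, tm):
    t1, t2, t3, t4 = Y[..., 0], Y[..., 1], Y[..., 2], Y[..., 3]
    u = 1.0 - (t1 + t2) / tc
    v = 1.0 - (t3 + t4) / tm
    z = np.zeros_like(t1)
    j11 = -P["phi"] / tc - P["phi1"] + P["lam1"] * u - P["lam1"] * t1 / tc - P["mu1"]
    j12 = -P["phi"] / tc - P["lam1"] * t1 / tc
    j21 = P["phi1"] - P["lam2"] * t2 / tc
    j22 = P["lam2"] * u - P["lam2"] * t2 / tc - (P["phi4"] + P["phi8"]) * v - P["mu2"]
    j23 = (P["phi4"] + P["phi8"]) * t2 / tm
    j24 = j23
    j32 = P["phi4"] * v
    j33 = -P["phi4"] * t2 / tm - P["eps4"] + P["lam4"] * v - P["lam4"] * t3 / tm - P["mu4"]
    j34 = -P["phi4"] * t2 / tm - P["lam4"] * t3 / tm
    j42 = P["phi8"] * v
    j43 = -P["phi8"] * t2 / tm - P["lam8"] * t4 / tm
    j44 = -P["phi8"] * t2 / tm - P["eps8"] + P["lam8"] * v - P["lam8"] * t4 / tm - P["mu8"]
    rows = [
        np.stack([j11, j12, z, z], axis=-1),
        np.stack([j21, j22, j23, j24], axis=-1),
        np.stack([z, j32, j33, j34], axis=-1),
        np.stack([z, j42, j43, j44], axis=-1),
    ]
    return np.stack(rows, axis=-2)


def _newton_polish(Y, P, tc, tm, n_iter: int = 12):
    """Damped Newton on the 4-D system; steps shrink to preserve positivity."""
    Y = Y.copy()
    for _ in range(n_iter):
        F = _rhs_arrays(Y, P, tc, tm)
        J = _jacobian(Y, P, tc, tm)
        ok = np.all(np.isfinite(F), axis=-1) & np.all(np.isfinite(J), axis=(-2, -1))
        step = np.zeros_like(Y)
        if np.any(ok):
            try:
                step[ok] = np.linalg.solve(J[ok], -F[ok][..., None])[..., 0]
            except np.linalg.LinAlgError:
                # singular members: leave their step at zero
                for i in np.nonzero(ok)[0]:
                    try:
                        step[i] = np.linalg.solve(J[i], -F[i][:, None])[:, 0]
                    except np.linalg.LinAlgError:
                        pass
        # damp so no population drops below -10% of its value in one step
        new = Y + step
        scale = np.ones(Y.shape[0])
        bad = new < 0
        if np.any(bad):
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(step < 0, -0.9 * Y / np.where(step < 0, step, -1.0), np.inf)
            scale = np.clip(np.min(frac, axis=-1), 0.0, 1.0)
        Y = Y + step * scale[:, None]
    return Y


def _residual(Y, P, tc, tm):
    F = np.abs(_rhs_arrays(Y, P, tc, tm))
    G = _gross_flux(Y, P, tc, tm)
    floor = 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where((F == 0) & (G <= floor), 0.0, F / np.maximum(G, floor))
    r = np.where(np.isfinite(Y).all(axis=-1, keepdims=True), r, np.inf)
    return np.max(r, axis=-1)


def steady_state_batch(values: np.ndarray, caps: CarryingCapacities,
                       settings: SimulationSettings | None = None,
                       n_bisect: int = 60):
    """Quasi-steady states for a batch of parameter sets.

    Parameters
    ----------
    values : (n, 14) array
        Parameter sets in :data:`PARAM_NAMES` order.
    caps : CarryingCapacities
        Fixed capacities (scalars, or arrays broadcastable to n).

    Returns
    -------
    states : (n, 4) array (NaN where not converged)
    converged : (n,) bool array
    residual : (n,) array of relative fixed-point residuals
    """
    settings = settings or SimulationSettings()
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(PARAM_NAMES):
        raise ValueError(f"values must be (n, {len(PARAM_NAMES)})")
    P = {nm: values[:, i] for i, nm in enumerate(PARAM_NAMES)}
    tc = np.broadcast_to(np.asarray(caps.t_cort_max, dtype=float), values.shape[:1])
    tm = np.broadcast_to(np.asarray(caps.t_med_max, dtype=float), values.shape[:1])
    Y = _solve_uv(P, tc, tm, n_bisect=n_bisect)
    Y = np.where(np.isfinite(Y), Y, 0.0)
    Y = _newton_polish(Y, P, tc, tm)
    res = _residual(Y, P, tc, tm)
    conv = (res <= settings.ss_tol) & np.all(np.isfinite(Y) & (Y >= 0), axis=-1)
    states = np.where(conv[:, None], Y, np.nan)
    return states, conv, res


def steady_state(p: HomeostasisParams, caps: CarryingCapacities,
                 settings: SimulationSettings | None = None,
                 initial_state: ThymocyteState | None = None) -> SteadyStateResult:
    """Quasi-steady state of the four populations at fixed capacities.

    Default path: semi-analytic vacancy-pair reduction plus Newton polish.
    If that fails the residual test (or an explicit ``initial_state`` is
    given) the attractor is approached by forward integration over
    ``settings.max_time_days`` and polished with Newton.  Non-convergence
    is reported in the result rather than raised, because plausibility
    screening must be able to count failures.
    """
    settings = settings or SimulationSettings()
    P = {nm: np.array([getattr(p, nm)]) for nm in PARAM_NAMES}
    tc = np.array([float(caps.t_cort_max)])
    tm = np.array([float(caps.t_med_max)])

    def finish(Y):
        Y = _newton_polish(Y, P, tc, tm)
        res = float(_residual(Y, P, tc, tm)[0])
        y = Y[0]
        ok = res <= settings.ss_tol and np.all(np.isfinite(y)) and np.all(y >= -1e-9)
        if ok:
            return SteadyStateResult(ThymocyteState(*np.maximum(y, 0.0)), True, res)
        return None

    if initial_state is None:
        Y = _solve_uv(P, tc, tm)
        Y = np.where(np.isfinite(Y), Y, 0.0)
        result = finish(Y)
        if result is not None:
            return result
        y0 = np.full(4, 1e6)
    else:
        y0 = initial_state.as_array()

    sol = solve_ivp(lambda t, y: _rhs_arrays(y[None, :], P, tc, tm)[0],
                    (0.0, settings.max_time_days), y0, method="LSODA",
                    rtol=settings.rel_tol, atol=settings.abs_tol)
    if sol.success:
        result = finish(sol.y[:, -1][None, :].copy())
        if result is not None:
            return result
        res = float(_residual(sol.y[:, -1][None, :], P, tc, tm)[0])
        return SteadyStateResult(None, False, res)
    return SteadyStateResult(None, False, np.inf)


# --- age-course simulation ------------------------------------------------

@dataclass(frozen=True)
class AgeSeries:
    """Trajectory of the model along age, with capacities and output."""

    age: np.ndarray
    t_dn: np.ndarray
    t_dp: np.ndarray
    t_sp4: np.ndarray
    t_sp8: np.ndarray
    t_cort_max: np.ndarray
    t_med_max: np.ndarray
    thymic_output: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.age) <= 0):
            raise ValueError("ages must be strictly increasing")
        for f in fields(self):
            if not np.all(np.isfinite(getattr(self, f.name))):
                raise ValueError(f"non-finite values in AgeSeries.{f.name}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({f.name: getattr(self, f.name) for f in fields(self)})

    def output_at(self, age: float) -> float:
        """Thymic output at an age, linearly interpolated between grid points."""
        if age < self.age[0] or age > self.age[-1]:
            raise ValueError(f"age {age} outside simulated range "
                             f"[{self.age[0]}, {self.age[-1]}]")
        return float(np.interp(age, self.age, self.thymic_output))

    def state_at(self, age: float) -> ThymocyteState:
        vals = [float(np.interp(age, self.age, getattr(self, nm)))
                for nm in ("t_dn", "t_dp", "t_sp4", "t_sp8")]
        return ThymocyteState(*(max(v, 0.0) for v in vals))


def simulate(p: HomeostasisParams, inv: InvolutionParams | None = None,
             settings: SimulationSettings | None = None,
             age_start: float = 0.0, age_end: float = 90.0,
             initial_state: ThymocyteState | None = None) -> AgeSeries:
    """Integrate the model along age with involuting carrying capacities.

    Time runs in days; the capacities are re-evaluated continuously at
    ``age = age_start + t/days_per_year``.  Unless overridden, the initial
    condition is the quasi-steady state at the starting age's capacities.
    """
    inv = inv or InvolutionParams()
    settings = settings or SimulationSettings()
    if not (0.0 <= age_start < age_end <= 100.0):
        raise ValueError("require 0 <= age_start < age_end <= 100")

    if initial_state is None:
        ss = steady_state(p, capacities(age_start, inv), settings)
        if not ss.converged:
            raise RuntimeError("no steady state at the starting age; "
                               "supply initial_state explicitly")
        initial_state = ss.state

    dpy = settings.days_per_year

    def f(t, y):
        c = capacities(age_start + t / dpy, inv)
        return rhs(y, c, p)

    t_end = (age_end - age_start) * dpy
    sol = solve_ivp(f, (0.0, t_end), initial_state.as_array(), method="LSODA",
                    rtol=settings.rel_tol, atol=settings.abs_tol,
                    dense_output=True)
    if not sol.success:
        raise RuntimeError(f"integrator failed: {sol.message}")

    if settings.output_grid is not None:
        ages = np.asarray(settings.output_grid, dtype=float)
        if ages[0] < age_start or ages[-1] > age_end:
            raise ValueError("output_grid outside the simulated age span")
    else:
        n = max(2, int(round((age_end - age_start) / settings.output_step_years)) + 1)
        ages = np.linspace(age_start, age_end, n)
    Y = sol.sol((ages - age_start) * dpy)
    Y = np.maximum(Y, 0.0)  # guard against tolerance-level negative excursions
    caps_arr = capacities(ages, inv)
    return AgeSeries(
        age=ages,
        t_dn=Y[0], t_dp=Y[1], t_sp4=Y[2], t_sp8=Y[3],
        t_cort_max=np.broadcast_to(caps_arr.t_cort_max, ages.shape).copy(),
        t_med_max=np.broadcast_to(caps_arr.t_med_max, ages.shape).copy(),
        thymic_output=p.eps4 * Y[2] + p.eps8 * Y[3],
    )
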