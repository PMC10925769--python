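"""Virtual-population plausibility screening and admissible parameter ranges.

The calibration workflow samples the fourteen homeostasis rate constants by
Latin hypercube sampling (LHS, one draw per marginal stratum), solves every
set to quasi-steady state at fixed infant capacities, and keeps the sets
whose four populations all fall inside the observed physiological ranges
("physiologically plausible" sets).  Admissible per-parameter intervals are
obtained by one-at-a-time bisection around the baseline under the same
in-range requirement, and generalized bounds combine these model-based
intervals with experimentally derived ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .homeostasis import (CALIBRATION_INFANT_CAPACITIES, PARAM_NAMES,
                          HomeostasisParams, SimulationSettings,
                          steady_state, steady_state_batch)
from .involution import CarryingCapacities

__all__ = [
    "ParameterBounds",
    "PhysiologicalRanges",
    "ScreenOutcome",
    "ScanOptions",
    "EXPERIMENTAL_BOUNDS",
    "MODEL_BASED_BOUNDS",
    "GENERALIZED_BOUNDS",
    "lhs_sample",
    "screen",
    "admissible_range",
    "combine_bounds",
]

_POPS = ("t_dn", "t_dp", "t_sp4", "t_sp8")


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter (lower, upper) intervals for the homeostasis constants."""

    intervals: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.intervals)
        if missing:
            raise ValueError(f"bounds missing for parameters: {sorted(missing)}")
        for nm, (lo, hi) in self.intervals.items():
            if nm not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {nm!r}")
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid interval for {nm}: [{lo}, {hi}]")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.intervals[name]

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.intervals[nm][0] for nm in PARAM_NAMES])
        hi = np.array([self.intervals[nm][1] for nm in PARAM_NAMES])
        return lo, hi


#: Intervals derived from published kinetic measurements (mouse-to-human
#: scaled where needed); shipped as constants.
EXPERIMENTAL_BOUNDS = ParameterBounds({
    "phi": (1e4, 4.8e5), "phi1": (0.18, 8.20), "mu1": (0.049, 0.056),
    "mu2": (0.25, 3.05), "lam1": (1.67, 3.33), "lam2": (3.125, 5.988),
    "phi4": (0.004, 1.930), "phi8": (0.002, 0.960), "lam4": (0.19, 0.22),
    "lam8": (0.19, 0.22), "mu4": (0.0, 0.06), "mu8": (0.0, 0.12),
    "eps4": (0.06, 0.23), "eps8": (0.06, 0.22),
})

#: Admissible intervals from the local (one-at-a-time) sensitivity analysis;
#: a zero lower bound marks "no violation found while decreasing to zero".
MODEL_BASED_BOUNDS = ParameterBounds({
    "phi": (0.0, 8.1e7), "phi1": (0.2066, 0.2168), "mu1": (0.053, 0.063),
    "mu2": (0.487, 0.507), "lam1": (1.627, 1.693), "lam2": (3.106, 3.233),
    "phi4": (0.491, 1.042), "phi8": (0.233, 0.505), "lam4": (0.0, 0.877),
    "lam8": (0.0, 1.338), "mu4": (0.0, 0.029), "mu8": (0.0, 0.022),
    "eps4": (0.046, 0.084), "eps8": (0.036, 0.077),
})

#: The combination of the two (see :func:`combine_bounds`); default LHS space.
GENERALIZED_BOUNDS = ParameterBounds({
    "phi": (1e4, 8.1e7), "phi1": (0.2066, 0.2168), "mu1": (0.053, 0.063),
    "mu2": (0.487, 0.507), "lam1": (1.627, 1.693), "lam2": (3.106, 3.233),
    "phi4": (0.491, 1.042), "phi8": (0.233, 0.505), "lam4": (0.19, 0.877),
    "lam8": (0.19, 1.338), "mu4": (0.0, 0.029), "mu8": (0.0, 0.022),
    "eps4": (0.046, 0.084), "eps8": (0.036, 0.077),
})


@dataclass(frozen=True)
class PhysiologicalRanges:
    """Observed infant cell-count intervals for each population, cells."""

    dn: tuple[float, float] = (1.3e9, 3.4e9)
    dp: tuple[float, float] = (1.2e10, 3.2e10)
    sp4: tuple[float, float] = (6.3e9, 1.7e10)
    sp8: tuple[float, float] = (2.3e9, 6.0e9)

    def __post_init__(self) -> None:
        for nm in ("dn", "dp", "sp4", "sp8"):
            lo, hi = getattr(self, nm)
            if not (0 < lo < hi):
                raise ValueError(f"invalid range for {nm}: [{lo}, {hi}]")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.dn[0], self.dp[0], self.sp4[0], self.sp8[0]])
        hi = np.array([self.dn[1], self.dp[1], self.sp4[1], self.sp8[1]])
        return lo, hi

    def contains(self, state) -> bool:
        lo, hi = self.as_arrays()
        y = state.as_array() if hasattr(state, "as_array") else np.asarray(state)
        return bool(np.all((y >= lo) & (y <= hi)))


@dataclass(frozen=True)
class ScreenOutcome:
    """Per-set verdicts plus summary counts of a plausibility screen."""

    results: pd.DataFrame
    n_total: int
    n_converged: int
    n_plausible: int

    @property
    def plausible_sets(self) -> pd.DataFrame:
        """Parameter values of the plausible sets only."""
        return self.results.loc[self.results["plausible"], list(PARAM_NAMES)]


def lhs_sample(bounds: ParameterBounds, n: int, seed: int) -> pd.DataFrame:
    """Latin hypercube draw: one value per equal-width stratum per parameter.

    Marginals are independent uniform; the pairing of strata across
    parameters is randomized by the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=len(PARAM_NAMES), seed=seed)
    unit = sampler.random(n)
    lo, hi = bounds.as_arrays()
    # scale by hand: degenerate (lower == upper) intervals are allowed
    return pd.DataFrame(lo + unit * (hi - lo), columns=list(PARAM_NAMES))


def screen(sets: pd.DataFrame, ranges: PhysiologicalRanges | None = None,
           caps: CarryingCapacities = CALIBRATION_INFANT_CAPACITIES,
           settings: SimulationSettings | None = None) -> ScreenOutcome:
    """Solve every parameter set to steady state and judge plausibility.

    A set is plausible iff the steady-state solve converged *and* all four
    populations lie inside their physiological ranges; solver failures are
    counted, never dropped.
    """
    ranges = ranges or PhysiologicalRanges()
    settings = settings or SimulationSettings()
    values = sets[list(PARAM_NAMES)].to_numpy(dtype=float)
    states, conv, res = steady_state_batch(values, caps, settings)
    lo, hi = ranges.as_arrays()
    with np.errstate(invalid="ignore"):
        in_range = (states >= lo) & (states <= hi)
    in_range &= conv[:, None]
    plausible = conv & np.all(in_range, axis=-1)
    out = sets.reset_index(drop=True).copy()
    for i, nm in enumerate(_POPS):
        out[nm] = states[:, i]
        out[f"in_range_{nm}"] = in_range[:, i]
    out["converged"] = conv
    out["residual"] = res
    out["plausible"] = plausible
    return ScreenOutcome(out, len(out), int(conv.sum()), int(plausible.sum()))


@dataclass(frozen=True)
class ScanOptions:
    """Bisection controls for one-at-a-time admissible-range scans."""

    rel_tol: float = 1e-4
    upper_factor: float = 100.0
    lower_floor: float = 0.0


def _plausible_point(p: HomeostasisParams, ranges, caps, settings) -> bool:
    ss = steady_state(p, caps, settings)
    return ss.converged and ranges.contains(ss.state)


def admissible_range(param_name: str, baseline: HomeostasisParams | None = None,
                     ranges: PhysiologicalRanges | None = None,
                     caps: CarryingCapacities = CALIBRATION_INFANT_CAPACITIES,
                     settings: SimulationSettings | None = None,
                     scan: ScanOptions = ScanOptions()) -> tuple[float, float]:
    """Largest one-at-a-time interval keeping all populations in range.

    The named parameter is varied with every other parameter at baseline;
    bisection finds the plausibility boundary on each side.  A bound not
    reached within the scan limits is reported at the limit; in particular
    a lower bracket that collapses onto the scan floor within the bisection
    resolution is reported as the floor itself (the bound is indeterminate,
    conventionally zero).
    """
    if param_name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {param_name!r}")
    baseline = baseline or HomeostasisParams()
    ranges = ranges or PhysiologicalRanges()
    settings = settings or SimulationSettings()
    base_val = getattr(baseline, param_name)

    def plaus(v: float) -> bool:
        return _plausible_point(replace(baseline, **{param_name: v}), ranges, caps, settings)

    if not plaus(base_val):
        raise ValueError("baseline parameter set is not plausible")

    step = scan.rel_tol * max(base_val, 1e-12)

    # upper bound
    hi_limit = base_val * scan.upper_factor if base_val > 0 else scan.upper_factor
    if plaus(hi_limit):
        upper = hi_limit
    else:
        lo, hi = base_val, hi_limit
        while hi - lo > step:
            mid = 0.5 * (lo + hi)
            if plaus(mid):
                lo = mid
            else:
                hi = mid
        upper = lo

    # lower bound
    lo_limit = scan.lower_floor
    if plaus(lo_limit):
        lower = lo_limit
    else:
        lo, hi = lo_limit, base_val
        while hi - lo > step:
            mid = 0.5 * (lo + hi)
            if plaus(mid):
                hi = mid
            else:
                lo = mid
        # bracket collapsed onto the floor: bound indeterminate, report floor
        lower = lo_limit if hi - lo_limit <= 2 * step else hi
    return lower, upper


def combine_bounds(experimental: ParameterBounds,
                   model_based: ParameterBounds) -> ParameterBounds:
    """Generalize bounds: model-based interval, except that an indeterminate
    (zero) model-based lower bound is replaced by the experimental one."""
    out = {}
    for nm in PARAM_NAMES:
        e_lo, _ = experimental[nm]
        m_lo, m_hi = model_based[nm]
        lo = e_lo if m_lo == 0.0 else m_lo
        out[nm] = (lo, m_hi)
    return ParameterBounds(out)
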