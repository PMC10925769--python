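"""Seeded synthetic-data generators.

Real calibration series for the involution curves (wet weight, TES
proportion, cortico-medullary ratio, density, volume) come from published
cross-sectional morphometry; these generators emulate their structure —
ages spanning 0-90 years, denser below 10 where the curves move fastest,
with positive right-skewed measurement scatter — from known generating
parameters, so that fitting code can be exercised and parameter recovery
quantified without any external data.

Noise models: multiplicative lognormal (default for counts/proportions:
positive, right-skewed, constant CV) or additive normal (for weights and
other symmetric measurement error).  Every generator is deterministic
under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .homeostasis import HomeostasisParams, SimulationSettings, simulate
from .involution import (CalibrationSeries, InvolutionParams, MorphometryParams,
                         SERIES_KINDS, cm_ratio, tes_fraction, wet_weight)

__all__ = ["NoiseSpec", "default_age_grid", "gen_involution_series",
           "gen_count_series"]

NOISE_KINDS = ("none", "multiplicative_lognormal", "additive_normal")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic series."""

    kind: str = "multiplicative_lognormal"
    cv_or_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; one of {NOISE_KINDS}")
        if self.cv_or_sd < 0:
            raise ValueError("cv_or_sd must be non-negative")

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.kind == "none" or self.cv_or_sd == 0:
            return np.array(values, dtype=float, copy=True)
        rng = np.random.default_rng(self.seed)
        if self.kind == "multiplicative_lognormal":
            # lognormal with unit median and sigma such that sd/mean ~ cv
            sigma = np.sqrt(np.log1p(self.cv_or_sd ** 2))
            return values * rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                          size=np.shape(values))
        return values + rng.normal(0.0, self.cv_or_sd, size=np.shape(values))


def default_age_grid(n: int = 30, age_max: float = 90.0) -> np.ndarray:
    """Age grid mirroring typical involution data: dense below 10 years."""
    n_young = max(n // 3, 2)
    young = np.linspace(0.0, 10.0, n_young, endpoint=False)
    older = np.linspace(10.0, age_max, n - n_young)
    return np.concatenate([young, older])


def gen_involution_series(truth: InvolutionParams | MorphometryParams,
                          kind: str, ages=None,
                          noise: NoiseSpec = NoiseSpec(kind="none")) -> CalibrationSeries:
    """Evaluate the true curve of the given kind and apply the noise model."""
    if kind not in SERIES_KINDS:
        raise ValueError(f"unknown series kind {kind!r}; one of {SERIES_KINDS}")
    ages = default_age_grid() if ages is None else np.asarray(ages, dtype=float)
    if np.any(ages < 0) or np.any(ages > 100):
        raise ValueError("ages must lie within [0, 100]")
    if kind in ("wet_weight", "tes_fraction", "cm_ratio"):
        if not isinstance(truth, InvolutionParams):
            raise TypeError(f"{kind} series requires InvolutionParams")
        fn = {"wet_weight": wet_weight, "tes_fraction": tes_fraction,
              "cm_ratio": cm_ratio}[kind]
        values = fn(ages, truth)
    else:
        if not isinstance(truth, MorphometryParams):
            raise TypeError(f"{kind} series requires MorphometryParams")
        values = truth.density(ages) if kind == "density" else truth.volume(ages)
    noisy = noise.apply(np.asarray(values, dtype=float))
    noisy = np.maximum(noisy, np.finfo(float).tiny)  # keep series valid
    return CalibrationSeries(ages, noisy, kind)


def gen_count_series(p: HomeostasisParams | None = None,
                     inv: InvolutionParams | None = None,
                     ages=None, noise: NoiseSpec = NoiseSpec(kind="none"),
                     settings: SimulationSettings | None = None) -> pd.DataFrame:
    """Observation-like table of relative DN/DP/SP proportions and totals.

    Simulates the age course and samples it at the requested ages; noise is
    applied per cell population and the proportions are renormalized to sum
    to one.  Columns: age, frac_dn, frac_dp, frac_sp, total.
    """
    p = p or HomeostasisParams()
    inv = inv or InvolutionParams()
    ages = np.arange(0.0, 91.0, 5.0) if ages is None else np.asarray(ages, dtype=float)
    grid = np.unique(np.concatenate([[0.0], ages]))
    settings = settings or SimulationSettings()
    from dataclasses import replace
    settings = replace(settings, output_grid=None,
                       output_step_years=min(settings.output_step_years, 0.25))
    series = simulate(p, inv, settings, age_start=float(grid[0]),
                      age_end=float(max(grid[-1], grid[0] + 1.0)))
    pops = np.stack([np.interp(ages, series.age, getattr(series, nm))
                     for nm in ("t_dn", "t_dp", "t_sp4", "t_sp8")], axis=-1)
    noisy = noise.apply(pops)
    noisy = np.maximum(noisy, 0.0)
    total = noisy.sum(axis=-1)
    frac = noisy / total[:, None]
    return pd.DataFrame({
        "age": ages,
        "frac_dn": frac[:, 0],
        "frac_dp": frac[:, 1],
        "frac_sp": frac[:, 2] + frac[:, 3],
        "total": total,
    })
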