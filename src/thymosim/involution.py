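"""Age-dependent thymic involution sub-model.

The thymus loses mass and thymopoietic capacity from the first year of life
onward.  This module describes that decline with three empirical curves —

* wet weight ``WW(age) = WW_BL * (1 - age^g / (age^g + EC50^g))`` (inverse
  Hill),
* thymic epithelial space proportion ``TES(age) = b_tes * exp(-k_tes*age)``,
* cortico-medullary ratio ``CM(age) = b_cm * exp(-k_cm*age)``,

and combines them into the maximal allowable thymocyte numbers (carrying
capacities) of the cortex and the medulla:

    T_cort_max(age) = T0 * CM/(CM+1) * [WW(age)*TES(age)] / [WW(0)*TES(0)]
    T_med_max(age)  = T0 * 1/(CM+1)  * [WW(age)*TES(age)] / [WW(0)*TES(0)]

where ``T0`` is the total thymocyte count in infants.  The cortex shrinks
faster than the medulla because ``CM`` itself decays with age.

The module also provides the morphometric transform used for validation
against relative cortex-volume data, and nonlinear least-squares fitting of
every curve with standard errors and relative standard errors (RSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.optimize import curve_fit

__all__ = [
    "InvolutionParams",
    "MorphometryParams",
    "CarryingCapacities",
    "CalibrationSeries",
    "FitResult",
    "SERIES_KINDS",
    "AGE_MAX",
    "wet_weight",
    "tes_fraction",
    "cm_ratio",
    "capacities",
    "infant_capacities",
    "relative_cortex_volume",
    "fit_involution",
]

#: Supported age domain in years.  The linear density/volume forms become
#: non-physical far outside the span of the underlying data.
AGE_MAX = 100.0

SERIES_KINDS = ("wet_weight", "tes_fraction", "cm_ratio", "density", "volume")


@dataclass(frozen=True)
class InvolutionParams:
    """Constants of the involution curves.

    Defaults are the calibrated estimates for human data; ``t0`` defaults to
    the midpoint of the infant total-thymocyte range [2.2e10; 5.8e10].

    Attributes
    ----------
    ww_bl : float
        Thymus wet weight at age 0, grams.
    ec50 : float
        Age of half-maximal weight loss, years.
    gamma : float
        Hill coefficient (dimensionless).
    b_tes, k_tes : float
        TES proportion at age 0 (percent) and its decay slope (1/year).
    b_cm, k_cm : float
        Cortico-medullary ratio at age 0 (dimensionless) and its decay
        slope (1/year).
    t0 : float
        Total thymocyte count in infants, cells.
    """

    ww_bl: float = 20.652
    ec50: float = 94.729
    gamma: float = 3.721
    b_tes: float = 93.344
    k_tes: float = 0.035
    b_cm: float = 2.77
    k_cm: float = 0.035
    t0: float = 4.0e10

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"InvolutionParams.{f.name} must be strictly "
                                 f"positive and finite, got {v!r}")


@dataclass(frozen=True)
class MorphometryParams:
    """Linear age models of thymic tissue density and volume.

    ``Dens(age) = k_d*age + b_d`` (g/cm^3), ``Vol(age) = k_v*age + b_v``
    (cm^3).  Slopes may be negative; both curves must stay positive over
    [0, AGE_MAX].

    The defaults are synthetic plausible values (tissue density slightly
    above water, declining as adipose tissue replaces parenchyma; a
    shrinking organ volume); they are not calibrated estimates.
    """

    k_d: float = -0.0005
    b_d: float = 1.05
    k_v: float = -0.15
    b_v: float = 30.0

    def __post_init__(self) -> None:
        if self.b_d <= 0 or self.b_v <= 0:
            raise ValueError("b_d and b_v must be positive")
        for k, b, name in ((self.k_d, self.b_d, "Dens"), (self.k_v, self.b_v, "Vol")):
            if min(b, k * AGE_MAX + b) <= 0:
                raise ValueError(f"{name}(age) must stay positive on [0, {AGE_MAX}]")

    def density(self, age):
        return self.k_d * np.asarray(age, dtype=float) + self.b_d

    def volume(self, age):
        return self.k_v * np.asarray(age, dtype=float) + self.b_v


@dataclass(frozen=True)
class CarryingCapacities:
    """Maximal thymocyte numbers in the cortex and the medulla, cells."""

    t_cort_max: float
    t_med_max: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.t_cort_max) <= 0) or np.any(np.asarray(self.t_med_max) <= 0):
            raise ValueError("carrying capacities must be positive")


@dataclass(frozen=True)
class CalibrationSeries:
    """A single calibration data series: (age, value) pairs of one kind."""

    ages: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ages", np.asarray(self.ages, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.kind not in SERIES_KINDS:
            raise ValueError(f"unknown series kind {self.kind!r}; expected one of {SERIES_KINDS}")
        if self.ages.shape != self.values.shape or self.ages.ndim != 1:
            raise ValueError("ages and values must be 1-D arrays of equal length")
        if np.any(self.ages < 0):
            raise ValueError("ages must be non-negative")
        if np.any(self.values <= 0):
            raise ValueError("values must be positive")

    def __len__(self) -> int:
        return self.ages.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "value": self.values, "kind": self.kind})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CalibrationSeries":
        kinds = frame["kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"series must hold a single kind, got {list(kinds)}")
        return cls(frame["age"].to_numpy(), frame["value"].to_numpy(), str(kinds[0]))

    @classmethod
    def read_csv(cls, path) -> "CalibrationSeries":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class FitResult:
    """Nonlinear-regression result with parameter uncertainty.

    ``rse_percent[k] == 100 * se[k] / estimates[k]``; a fit is considered
    acceptable when every RSE is below 50%.
    """

    estimates: Mapping[str, float]
    se: Mapping[str, float]
    rse_percent: Mapping[str, float]
    converged: bool
    residual_sum_squares: float
    kind: str = ""

    @property
    def acceptable(self) -> bool:
        return self.converged and all(r < 50.0 for r in self.rse_percent.values())


def _check_age(age) -> np.ndarray:
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    return a


def wet_weight(age, p: InvolutionParams = InvolutionParams()):
    """Thymus wet weight WW(age) in grams (inverse Hill decline)."""
    a = _check_age(age)
    hill = a ** p.gamma / (a ** p.gamma + p.ec50 ** p.gamma)
    return p.ww_bl * (1.0 - hill)


def tes_fraction(age, p: InvolutionParams = InvolutionParams()):
    """Relative proportion of the thymic epithelial space, percent."""
    a = _check_age(age)
    return p.b_tes * np.exp(-p.k_tes * a)


def cm_ratio(age, p: InvolutionParams = InvolutionParams()):
    """Cortico-medullary ratio CM(age), dimensionless."""
    a = _check_age(age)
    return p.b_cm * np.exp(-p.k_cm * a)


def capacities(age, p: InvolutionParams = InvolutionParams()) -> CarryingCapacities:
    """Cortex and medulla carrying capacities at a given age.

    By construction ``t_cort_max / t_med_max == cm_ratio(age)`` and
    ``t_cort_max + t_med_max == t0 * WW(age)*TES(age) / (WW(0)*TES(0))``.
    """
    a = _check_age(age)
    rel = (wet_weight(a, p) * tes_fraction(a, p)) / (p.ww_bl * p.b_tes)
    cm = cm_ratio(a, p)
    total = p.t0 * rel
    return CarryingCapacities(total * cm / (cm + 1.0), total / (cm + 1.0))


#: Number of quadrature nodes for the infant (0-to-1 year) average.
_INFANT_QUAD_POINTS = 21


def infant_capacities(p: InvolutionParams = InvolutionParams()) -> CarryingCapacities:
    """Mean carrying capacities over the 0-to-1-year age window.

    Computed as the integral average of :func:`capacities` over age in
    [0, 1] by 21-point composite Simpson quadrature (the curves are smooth,
    so the scheme choice matters at <0.1%).
    """
    ages = np.linspace(0.0, 1.0, _INFANT_QUAD_POINTS)
    c = capacities(ages, p)
    return CarryingCapacities(
        float(simpson(c.t_cort_max, x=ages)),
        float(simpson(c.t_med_max, x=ages)),
    )


def relative_cortex_volume(age, p: InvolutionParams = InvolutionParams(),
                           m: MorphometryParams = MorphometryParams()):
    """Relative cortex volume, normalized to the infant (0-1 y) mean.

    Morphometric transform of the cortex capacity for comparison against
    cortex-volume data: CM/(CM+1) * WW*TES / Dens / Vol, divided by its
    own 0-to-1-year average so the infant reference equals 1.
    """
    a = _check_age(age)
    if np.any(a > AGE_MAX):
        raise ValueError(f"age beyond the supported domain [0, {AGE_MAX}]")

    def raw(aa):
        dens = m.density(aa)
        vol = m.volume(aa)
        if np.any(dens <= 0) or np.any(vol <= 0):
            raise ValueError("density/volume non-positive at requested age")
        cm = cm_ratio(aa, p)
        return cm / (cm + 1.0) * wet_weight(aa, p) * tes_fraction(aa, p) / dens / vol

    ref_ages = np.linspace(0.0, 1.0, _INFANT_QUAD_POINTS)
    ref = simpson(raw(ref_ages), x=ref_ages)
    return raw(a) / ref


# --- nonlinear regression -------------------------------------------------

def _hill_model(age, ww_bl, ec50, gamma):
    return ww_bl * (1.0 - age ** gamma / (age ** gamma + ec50 ** gamma))


def _exp_model_factory(bname, kname):
    def model(age, b, k):
        return b * np.exp(-k * age)
    model.param_names = (bname, kname)
    return model


def _linear_model_factory(kname, bname):
    def model(age, k, b):
        return k * age + b
    model.param_names = (kname, bname)
    return model


def _p0_hill(ages, values):
    top = float(np.max(values))
    half = top / 2.0
    below = ages[values <= half]
    ec50 = float(below.min()) if below.size else float(np.max(ages))
    return [top, max(ec50, 1.0), 2.0]


def _p0_exp(ages, values):
    # log-linear heuristic for b * exp(-k age)
    k, logb = np.polyfit(ages, -np.log(values), 1)
    return [float(np.exp(-logb)), float(k)]


def _p0_linear(ages, values):
    k, b = np.polyfit(ages, values, 1)
    return [float(k), float(b)]


_MODELS = {
    "wet_weight": (_hill_model, ("ww_bl", "ec50", "gamma"), _p0_hill),
    "tes_fraction": (_exp_model_factory("b_tes", "k_tes"), ("b_tes", "k_tes"), _p0_exp),
    "cm_ratio": (_exp_model_factory("b_cm", "k_cm"), ("b_cm", "k_cm"), _p0_exp),
    "density": (_linear_model_factory("k_d", "b_d"), ("k_d", "b_d"), _p0_linear),
    "volume": (_linear_model_factory("k_v", "b_v"), ("k_v", "b_v"), _p0_linear),
}


def fit_involution(series: CalibrationSeries, model_kind: str | None = None,
                   weighting: str = "relative") -> FitResult:
    """Least-squares fit of one involution/morphometry curve.

    With the default ``weighting="relative"`` the fit is iteratively
    reweighted with standard deviations proportional to the model-predicted
    values — appropriate for positive morphometric measurements whose
    scatter has roughly constant coefficient of variation, and required for
    the reported standard errors to be calibrated under such noise.
    ``weighting="absolute"`` performs plain unweighted least squares.
    Either way the covariance is the reduced-chi-square-scaled
    Jacobian-based estimate at the optimum, and RSE is 100*SE/estimate.

    Raises
    ------
    ValueError
        If the series has fewer distinct ages than parameters + 1, or the
        optimizer fails to converge.
    """
    kind = model_kind or series.kind
    if kind not in _MODELS:
        raise ValueError(f"unknown model kind {kind!r}")
    if weighting not in ("relative", "absolute"):
        raise ValueError("weighting must be 'relative' or 'absolute'")
    model, names, p0_fn = _MODELS[kind]
    ages, values = series.ages, series.values
    n, npar = ages.size, len(names)
    if np.unique(ages).size < npar + 1:
        raise ValueError(
            f"need at least {npar + 1} distinct ages to fit {kind} ({np.unique(ages).size} given)")
    try:
        p0 = p0_fn(ages, values)
    except Exception:
        p0 = [1.0] * npar
    try:
        sigma = values if weighting == "relative" else None
        popt, pcov = curve_fit(model, ages, values, p0=p0, sigma=sigma, maxfev=20000)
        if weighting == "relative":
            # one reweight with model-predicted scale (IRLS step)
            pred = np.abs(model(ages, *popt))
            if np.all(pred > 0) and np.all(np.isfinite(pred)):
                popt, pcov = curve_fit(model, ages, values, p0=popt,
                                       sigma=pred, maxfev=20000)
        converged = bool(np.all(np.isfinite(popt)) and np.all(np.isfinite(pcov)))
    except RuntimeError as exc:
        raise ValueError(f"fit of {kind} did not converge: {exc}") from exc
    resid = values - model(ages, *popt)
    rss = float(resid @ resid)
    se = np.sqrt(np.diag(pcov))
    estimates = {nm: float(v) for nm, v in zip(names, popt)}
    se_map = {nm: float(s) for nm, s in zip(names, se)}
    rse = {nm: 100.0 * se_map[nm] / abs(estimates[nm]) if estimates[nm] != 0 else np.inf
           for nm in names}
    return FitResult(estimates, se_map, rse, converged, rss, kind=kind)


def params_from_fits(wet_weight_fit: FitResult, tes_fit: FitResult, cm_fit: FitResult,
                     t0: float = 4.0e10) -> InvolutionParams:
    """Assemble :class:`InvolutionParams` from three curve fits."""
    est = {**wet_weight_fit.estimates, **tes_fit.estimates, **cm_fit.estimates}
    return InvolutionParams(ww_bl=est["ww_bl"], ec50=est["ec50"], gamma=est["gamma"],
                            b_tes=est["b_tes"], k_tes=est["k_tes"],
                            b_cm=est["b_cm"], k_cm=est["k_cm"], t0=t0)
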