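"""Clinically relevant simulation scenarios.

Four presets are provided:

* ``healthy`` — egress rates at the healthy-subject values 0.076 (SP4) and
  0.082 (SP8) per day;
* ``early_involution`` — additionally shifts the involution half-age to
  EC50 = 40 years, emulating premature thymic involution as seen e.g. in
  multiple sclerosis;
* ``egress_block`` — egress lowered to 0.011/0.012 per day, the effect of
  an S1P-receptor modulator (fingolimod-like) that traps mature SP cells
  in the medulla; applied inside a treatment window when one is given,
  otherwise for the whole run;
* ``early_involution_block`` — both of the above.

Egress blockage is applied as a step change at the window edges (no
pharmacokinetic ramp).  The headline readout is thymic output, the SP
export rate in cells/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .homeostasis import (AgeSeries, HomeostasisParams, SimulationSettings,
                          ThymocyteState, simulate)
from .involution import InvolutionParams

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "SCENARIO_NAMES",
    "HEALTHY_EGRESS",
    "BLOCKED_EGRESS",
    "EARLY_INVOLUTION_EC50",
    "make_scenario",
    "run_scenario",
    "output_fold_difference",
    "time_to_threshold",
    "rebound",
]

HEALTHY_EGRESS = (0.076, 0.082)     # (eps4, eps8), 1/day
BLOCKED_EGRESS = (0.011, 0.012)     # under S1P-modulator treatment
EARLY_INVOLUTION_EC50 = 40.0        # years

SCENARIO_NAMES = ("healthy", "early_involution", "egress_block",
                  "early_involution_block")


@dataclass(frozen=True)
class ScenarioSpec:
    """Overrides applied on top of the base model for one scenario."""

    name: str
    ec50_override: Optional[float] = None
    eps4_override: Optional[float] = None
    eps8_override: Optional[float] = None
    treatment_start_age: Optional[float] = None
    treatment_duration: Optional[float] = None
    output_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        for nm in ("ec50_override", "eps4_override", "eps8_override"):
            v = getattr(self, nm)
            if v is not None and v <= 0:
                raise ValueError(f"{nm} must be positive when given")
        if (self.treatment_start_age is None) != (self.treatment_duration is None):
            raise ValueError("treatment window needs both start age and duration")
        if self.treatment_start_age is not None:
            if not (0 <= self.treatment_start_age
                    and self.treatment_start_age + self.treatment_duration <= 100
                    and self.treatment_duration >= 0):
                raise ValueError("treatment window must lie within ages [0, 100]")

    @property
    def window(self) -> Optional[tuple[float, float]]:
        if self.treatment_start_age is None:
            return None
        return (self.treatment_start_age,
                self.treatment_start_age + self.treatment_duration)


@dataclass(frozen=True)
class ScenarioResult:
    """A scenario trajectory plus the spec that produced it."""

    spec: ScenarioSpec
    series: AgeSeries
    untreated_series: Optional[AgeSeries] = None

    def output_at(self, age: float) -> float:
        return self.series.output_at(age)


def make_scenario(name: str, treatment_start_age: float | None = None,
                  treatment_duration: float | None = None,
                  output_threshold: float | None = None) -> ScenarioSpec:
    """Build a preset scenario spec by name."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; valid presets: {SCENARIO_NAMES}")
    eps4, eps8 = HEALTHY_EGRESS
    ec50 = None
    if name in ("early_involution", "early_involution_block"):
        ec50 = EARLY_INVOLUTION_EC50
    if name in ("egress_block", "early_involution_block"):
        eps4, eps8 = BLOCKED_EGRESS
    return ScenarioSpec(name=name, ec50_override=ec50,
                        eps4_override=eps4, eps8_override=eps8,
                        treatment_start_age=treatment_start_age,
                        treatment_duration=treatment_duration,
                        output_threshold=output_threshold)


def _concat_series(parts: list[AgeSeries]) -> AgeSeries:
    arrays = {}
    for nm in ("age", "t_dn", "t_dp", "t_sp4", "t_sp8",
               "t_cort_max", "t_med_max", "thymic_output"):
        chunks = []
        for i, s in enumerate(parts):
            a = getattr(s, nm)
            chunks.append(a if i == 0 else a[1:])  # drop duplicated joints
        arrays[nm] = np.concatenate(chunks)
    return AgeSeries(**arrays)


def run_scenario(spec: ScenarioSpec, base: HomeostasisParams | None = None,
                 inv: InvolutionParams | None = None,
                 settings: SimulationSettings | None = None,
                 age_start: float = 0.0, age_end: float = 90.0,
                 initial_state: ThymocyteState | None = None) -> ScenarioResult:
    """Simulate the age course with the scenario's overrides applied.

    Egress overrides apply only inside the treatment window when one is
    given (the base parameters' egress rates hold outside it); without a
    window they apply to the whole run.  An override-free spec reproduces
    the base simulation exactly.
    """
    base = base or HomeostasisParams()
    inv = inv or InvolutionParams()
    settings = settings or SimulationSettings()
    if spec.ec50_override is not None:
        inv = replace(inv, ec50=spec.ec50_override)

    def with_eps(p: HomeostasisParams) -> HomeostasisParams:
        kw = {}
        if spec.eps4_override is not None:
            kw["eps4"] = spec.eps4_override
        if spec.eps8_override is not None:
            kw["eps8"] = spec.eps8_override
        return replace(p, **kw) if kw else p

    window = spec.window
    if window is None:
        series = simulate(with_eps(base), inv, settings, age_start, age_end,
                          initial_state=initial_state)
        return ScenarioResult(spec, series)

    t_on = min(max(window[0], age_start), age_end)
    t_off = min(max(window[1], age_start), age_end)
    edges = [age_start, t_on, t_off, age_end]
    params = [base, with_eps(base), base]
    parts: list[AgeSeries] = []
    state = initial_state
    for (a0, a1), p in zip(zip(edges[:-1], edges[1:]), params):
        if a1 <= a0:
            continue
        seg = simulate(p, inv, settings, a0, a1, initial_state=state)
        state = seg.state_at(a1)
        parts.append(seg)
    return ScenarioResult(spec, _concat_series(parts))


def output_fold_difference(a: ScenarioResult, b: ScenarioResult, age: float) -> float:
    """Ratio of thymic outputs a/b at an age (linear interpolation)."""
    return a.output_at(age) / b.output_at(age)


def time_to_threshold(spec: ScenarioSpec, base: HomeostasisParams | None = None,
                      inv: InvolutionParams | None = None,
                      settings: SimulationSettings | None = None,
                      threshold: float | None = None,
                      start_age: float = 20.0) -> float | None:
    """Years after ``start_age`` until thymic output falls below a threshold.

    Returns ``None`` ("never") when the trajectory does not cross the
    threshold before age 100.  The crossing is located by bisection on the
    simulated trajectory between the bracketing grid points.
    """
    if threshold is None:
        threshold = spec.output_threshold
    if threshold is None or threshold < 0:
        raise ValueError("a non-negative output threshold is required")
    result = run_scenario(spec, base, inv, settings,
                          age_start=start_age, age_end=100.0)
    ages, out = result.series.age, result.series.thymic_output
    if out[0] < threshold:
        return 0.0
    below = np.nonzero(out < threshold)[0]
    if below.size == 0:
        return None
    i = below[0]
    lo, hi = ages[i - 1], ages[i]
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if float(np.interp(mid, ages, out)) < threshold:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi) - start_age


def rebound(spec: ScenarioSpec, base: HomeostasisParams | None = None,
            inv: InvolutionParams | None = None,
            settings: SimulationSettings | None = None,
            age_start: float = 0.0, age_end: float = 90.0) -> ScenarioResult:
    """Egress blockage with restoration, against a matched untreated run.

    The spec must carry a treatment window; after the window the base
    egress rates are restored and SP cells that accumulated toward the
    medullary capacity are exported, producing a transient output overshoot.
    The matched untreated trajectory (same spec without the egress
    overrides) is attached for rebound metrics.
    """
    if spec.window is None:
        raise ValueError("rebound requires a treatment window")
    treated = run_scenario(spec, base, inv, settings, age_start, age_end)
    untreated_spec = replace(spec, eps4_override=None, eps8_override=None)
    untreated = run_scenario(untreated_spec, base, inv, settings, age_start, age_end)
    return ScenarioResult(spec, treated.series, untreated_series=untreated.series)


def rebound_magnitude(result: ScenarioResult) -> tuple[float, float]:
    """(peak excess output, age of peak) after egress restoration.

    Excess is treated minus matched untreated output at the same age,
    evaluated from the end of the treatment window onward.
    """
    if result.untreated_series is None or result.spec.window is None:
        raise ValueError("result must come from rebound()")
    t_off = result.spec.window[1]
    s = result.series
    mask = s.age >= t_off
    excess = s.thymic_output[mask] - np.array(
        [result.untreated_series.output_at(a) for a in s.age[mask]])
    i = int(np.argmax(excess))
    return float(excess[i]), float(s.age[mask][i])
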