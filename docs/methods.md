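# Methods

## Model structure and assumptions

The model is a deterministic four-compartment ODE system for DN, DP, SP4
and SP8 thymocyte counts (cells), with rate constants in day⁻¹.  Its
structural assumptions:

* DN and DP cells compete for cortical space, SP4 and SP8 for medullary
  space.  Crowding acts through logistic vacancy factors (1−x) and (1−y)
  on precursor inflow, proliferation, and the DP→SP transition (the
  transition is gated by *medullary* vacancy: differentiated cells must
  find room in the medulla).
* Death (μ), differentiation out of DN (φ₁) and egress (ε) are first
  order and not crowding-limited.
* The equations are integrated exactly as written: vacancy factors are
  not clamped, so transiently overcrowded states produce negative inflow
  and proliferation terms.  This is intentional; it makes the fixed-point
  algebra exact.
* Involution is purely a property of the niches: the age-dependent
  capacities T_cort_max(age), T_med_max(age) decline, while the cellular
  rate constants are age-invariant.  No TREC bookkeeping, no tTreg
  lineage, no re-entry of peripheral lymphocytes, no stochasticity.

Time runs in days internally; ages in years with 365 days/year (the
conversion is a setting).  The supported age domain is [0, 100] years —
the linear density/volume morphometry becomes non-physical far outside
the data span.

## Parameters

`HomeostasisParams` defaults are the calibrated baseline: φ = 4.8×10⁵
cells/day precursor inflow; φ₁ = 0.21, φ₄ = 0.8, φ₈ = 0.3 day⁻¹
differentiation; λ₁ = 1.67, λ₂ = 3.125, λ₄ = λ₈ = 0.22 day⁻¹
proliferation; μ₁ = 0.056, μ₂ = 0.5, μ₄ = μ₈ = 0.005 day⁻¹ death;
ε₄ = ε₈ = 0.06 day⁻¹ egress.  `InvolutionParams` defaults are the
calibrated involution estimates (WW_BL = 20.652 g, EC50 = 94.729 y,
γ = 3.721, b_tes = 93.344 %, k_tes = 0.035 y⁻¹, b_cm = 2.77,
k_cm = 0.035 y⁻¹).  TES is stored in percent; only the ratio
TES(age)/TES(0) enters the capacities, so the unit cancels (asserted by
test).

Two constants deserve comment:

* **T₀**, the total infant thymocyte count, is only known as a range
  [2.2×10¹⁰; 5.8×10¹⁰]; the default is the midpoint 4.0×10¹⁰, which
  reproduces the fixed infant capacities (below) within a few percent.
  It is a plain config field.
* **Infant capacities.**  The homeostasis model was calibrated against
  fixed infant capacities (2.84×10¹⁰ cortex, 1.05×10¹⁰ medulla), shipped
  as `CALIBRATION_INFANT_CAPACITIES` and used for steady-state
  reproduction, screening and admissible-range scans.
  `infant_capacities()` recomputes the same quantity from the involution
  curves as the integral average of the capacities over ages 0–1
  (21-point composite Simpson; the scheme matters at <0.1%), giving
  (2.875×10¹⁰, 1.056×10¹⁰) at the default T₀ — the two agree within 2%,
  and the small gap is absorbed by the unknown exact T₀.

## Quasi-steady-state solver

At a fixed point the populations are rational functions of the vacancy
pair (u, v) = (1−x, 1−y):

    T_DN = φu / (φ₁+μ₁−λ₁u),  T_DP = φ₁T_DN / (μ₂+(φ₄+φ₈)v−λ₂u),
    T_SP4 = φ₄vT_DP / (ε₄+μ₄−λ₄v),  T_SP8 = φ₈vT_DP / (ε₈+μ₈−λ₈v).

On the positive branch all denominators are positive, which brackets u
and v; the cortex self-consistency residual is strictly decreasing in u,
so the problem reduces to two nested monotone bisections (60 iterations
each), followed by a damped Newton polish of the full 4-D system with the
analytic Jacobian.  The polish drives the fixed-point residual — the
largest |net rate| relative to that equation's gross production flux —
to ~10⁻¹⁵; convergence requires residual ≤ `ss_tol` (default 10⁻⁸).
Everything vectorizes across parameter sets: a 150,000-set screen takes
tens of seconds on one CPU.  When the reduction fails its residual test
(degenerate corners such as φ = 0) or the caller supplies an initial
state, the solver falls back to LSODA forward integration over 2×10⁴
days plus the same Newton polish, and reports non-convergence honestly
instead of raising — screening must be able to count failures.  The two
routes are cross-checked against each other on random parameter draws
(agreement within 0.1%).

A caveat worth knowing: the DN equation balances λ₁(1−x) against φ₁+μ₁,
a near-cancellation at the baseline, which makes the steady-state DN
count hypersensitive to rounding in φ₁, μ₁, λ₁ — DP and SP values are
robust to it, DN is reproduced only to ~15%.

## Age-course simulation and scenarios

`simulate` integrates in day units with LSODA (rel_tol 10⁻⁸), the
capacities re-evaluated continuously along age; the initial condition
defaults to the quasi-steady state at the starting age's capacities.
Output is sampled from the dense solution on a 0.25-year grid, with
tolerance-level negative excursions clamped to zero.

Scenario presets: healthy egress (ε₄, ε₈) = (0.076, 0.082) day⁻¹;
early-onset involution additionally sets EC50 = 40 y; egress blockage
(ε₄, ε₈) = (0.011, 0.012) day⁻¹, applied as a step change at the
treatment-window edges (no pharmacokinetic ramp), with the base rates
restored afterwards.  Scenario runs default to the baseline rate set with
the scenario's printed egress values; a user-computed plausible-set mean
can be substituted.  The lymphopenia-discontinuation threshold on thymic
output is a required input of `time_to_threshold`, not a shipped
constant — its derivation needs peripheral lymphocyte kinetics outside
this model's scope.  Crossing times are located by bisection on the
interpolated trajectory; "never before age 100" is returned as `None`.

## Screening, admissible ranges, PRCC

LHS uses `scipy.stats.qmc.LatinHypercube` (exactly one draw per marginal
stratum, independent uniform marginals, seeded).  Plausibility = solver
convergence **and** all four steady-state populations strictly inside the
physiological ranges DN [1.3; 3.4]×10⁹, DP [1.2; 3.2]×10¹⁰,
SP4 [0.63; 1.7]×10¹⁰, SP8 [2.3; 6.0]×10⁹ cells; non-converged sets count
as implausible.  Under the shipped generalized bounds about a quarter of
draws are plausible (the acceptance script computes the exact count).

Admissible ranges vary one parameter at a time from the baseline,
bisecting to the plausibility boundary (relative tolerance 10⁻⁴, upper
scan limit 100× baseline, lower floor 0).  A lower bracket that collapses
onto the floor within the bisection resolution is reported as the floor:
the bound is indeterminate — this reproduces the zero lower bounds of φ,
λ₄, λ₈, μ₄, μ₈.  Generalized bounds take the model-based interval,
substituting the experimental lower bound where the model-based one is
indeterminate.

PRCC rank-transforms all columns and the output, residualizes column j
and the output on all other columns by least squares, and correlates the
residuals; p-values use the t approximation with n−2−(k−1) degrees of
freedom.  An independent uniform dummy column provides the significance
floor: significant ⇔ p < α (default 0.05, two-sided) and |PRCC| >
|PRCC_dummy|.  The default output is the SP4+SP8 steady-state sum (the
thymic-function proxy); per-population outputs are available.  Because
egress and death necessarily correlate *negatively* with SP count,
"dominant parameter" statements compare |PRCC|.  The graphical
linearity/monotonicity check is replaced by a numerical report: Spearman
correlation overall and on the lower/upper halves of each parameter's
sampled range, flagging significantly opposite-signed halves (a centered
parabola is flagged; pure noise is not).

## Involution-curve regression

`fit_involution` uses Levenberg–Marquardt least squares
(`scipy.optimize.curve_fit`) with data-driven starting values (plateau =
max value; log-linear slope for the decays; straight-line fit for the
linear forms).  By default the fit is iteratively reweighted with
standard deviations proportional to the model prediction ("relative"
weighting): positive morphometric measurements scatter with roughly
constant CV, and under such noise unweighted SEs are badly
miscalibrated (±2 SE coverage ≈ 58% instead of 95% in the Monte-Carlo
test).  With relative weighting the coverage test passes (≥ 90% at
CV = 10%, n = 30, 200 replicates).  Covariance is the
reduced-χ²-scaled Jacobian estimate at the optimum; RSE = 100·SE/estimate
with RSE < 50% as the identifiability criterion.  Plain unweighted
fitting is available via `weighting="absolute"`.

## Synthetic data

The generators emulate cross-sectional involution series (ages 0–90,
denser below 10 years where the curves move fastest) and
observation-like tables of relative DN/DP/SP proportions and total
counts along the simulated age course.  Noise is multiplicative lognormal
by default (positive, right-skewed, constant CV — shaped like biological
count scatter), with an additive-normal mode for weight-like data; every
generator is deterministic under its seed.  What they deliberately do
*not* emulate: inter-study heterogeneity (different labs, assays and age
binnings of real curated data), sampling correlation across ages, and
measurement error in age itself.  Passing recovery tests on these data
therefore demonstrates correctness of the fitting machinery under the
assumed noise model, not robustness to real multi-source heterogeneity.

## Numerical choices and scales

Steady-state bisection depth 60 (≈10⁻¹⁸ relative bracket), Newton polish
12 iterations with step damping to preserve positivity; integrator
tolerances rel 10⁻⁸/abs 1 cell; quadrature 21-point Simpson on [0, 1].
Test-suite problem sizes are chosen for a desk machine: the full
150,000-set screen runs once (shared by the screening and PRCC
acceptance checks, ~1 min); cross-check properties use 100 random draws;
Monte-Carlo coverage uses 200 replicates of n = 30.

## Known limitations

* The screen's plausible-set *count* depends strongly on the sampled
  bounds (24% of draws under the generalized bounds vs ~0.1% under the
  wider experimental bounds); treat the plausible fraction as a property
  of the chosen bounds, not of the model.
* DN steady-state reproduction is limited to ~15% by the rounding
  sensitivity described above.
* One-at-a-time admissible ranges ignore parameter interactions by
  construction; jointly varied parameters can leave the ranges while
  each stays admissible alone.
* Morphometry defaults (density/volume lines) are synthetic plausible
  values for generator/validation-transform use, not calibrated
  estimates.
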