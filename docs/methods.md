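# Methods

This note documents the models, the numerical choices, and the known
limitations of each pipeline stage, in the order the method runs.

## Data and exposure standardization

All inputs are small printed tables shipped as package fixtures: three
occupational-study estimates with 95% CIs (RR 1.40, SMR 2.18, RR 1.63),
three rat inhalation bioassays as quantal dose groups, the confounding and
misclassification scenario grids, and the published benchmark-dose table
used where its values are exogenous inputs downstream.

Bioassay exposure regimens are standardized to a 30-month average
continuous concentration, C·(hours/week ÷ 168)·(months ÷ 30) μg/m³, a
metric proportional to cumulative exposure. The *rounded* published doses
(930, 2400, 270, 840, 2500, 73, 730, 1480 μg/m³) are canonical for all
fitting, because the published downstream arithmetic is keyed to them; the
exact formula (e.g. 929.5 rather than 930) is available for new regimens
and changes no conclusion (BMDs move by < 0.2%).

Two source inconsistencies are resolved in the fixtures: the
"% with lung tumors" column of the bioassay table is internally
inconsistent (for one study it repeats the chamber concentrations), so
fractions are always recomputed as n_affected/n_examined; and the
high-dose-control group size is taken from the table (250) rather than the
narrative text (288), again because the downstream arithmetic is keyed to
the table.

## Confounding sensitivity analysis

For a binary confounder with outcome rate ratio R (smokers vs non-smokers;
scenario values 10.7–19) and prevalence p, the population-averaged
incidence is I₀·m(p, R) with m(p, R) = pR + 1 − p. The bias factor
m(p_cohort, R)/m(p_reference, R) divides the observed estimate and both CI
limits — the factor is treated as a known constant, so the CI *ratio*
(upper/lower) is preserved while the interval shifts. This matches
back-calculation from the published grids (e.g. 1.30/1.128 = 1.153). No
exposure-confounder interaction is modelled; the underlying cohort data
could not support estimating one.

Scenario grids: railroad cohort, R ∈ {14,…,19} with prevalences fixed at
0.471/0.409; carbon-black cohort, R ∈ {10.7, 12.0} × reference prevalence
0.65–0.77 in steps of 0.02 with cohort prevalence 0.84 (14 cells). The
carbon-black arithmetic uses SMR 2.18 (its published CI row), treating a
stray "2.17" in the source narrative as a typo: 2.18/1.252 = 1.741
reproduces the published cell exactly, 2.17 does not.

## Misclassification Monte Carlo

Study constants: cohort-equivalent size N = 3,406 (1,042 cases + 2,364
referents), unexposed incidence I₀ = 842/(37.5·2,833) ≈ 0.0079 over an
average 37.5-year study period, observed top-quartile RR 1.63 (1.14–2.33).
The assumed true RR seeding the trials defaults to the observed 1.63.

Per trial, with n₁ = round(N·P_E) exposed and n₀ = N − n₁ unexposed:
case counts are Binomial(n₁, I₀·RR) and Binomial(n₀, I₀); the trial's true
RR uses the drawn counts over the fixed denominators; exposure is then
reclassified non-differentially — within cases and non-cases separately,
exposed→unexposed ~ Binomial(count, 1 − Se), unexposed→exposed ~
Binomial(count, 1 − Sp) — and the misclassified RR uses the reclassified
counts and denominators.

The source narrative never states how per-trial pairs become an adjusted
estimate. This implementation uses the standard simulation-correction
ratio: adjusted_t = RR_observed · (RR_true_t / RR_misclassified_t),
summarized by the median with a 2.5–97.5 percentile interval. Consequences
worth stating plainly:

- Se = Sp = 1 returns the observed 1.63 *exactly*, every trial. The
  published grid prints ≈ 1.70 in those cells, which no ratio-type
  construction can produce; the published values are therefore treated as
  ordering/magnitude references only, and the identity is asserted instead.
- In expected-count mode (every draw replaced by its expectation) the
  adjustment equals the closed-form misclassification-matrix correction,
  true_exposed = (observed_exposed − (1 − Sp)·total)/(Se + Sp − 1) applied
  within cases and non-cases, to 1e−10. The matrix inversion requires
  Se + Sp > 1; the *simulation* does not, and the scenario grid deliberately
  includes Se + Sp ≤ 1 cells as the published grid does.

Trials with a zero cell in either RR are discarded and counted (no
continuity correction); the discard count is part of the result. Scenario
RNG streams derive from (master seed, scenario index), so grids are
reproducible and order-independent. Draws are vectorized over trials.

## Multistage benchmark dose

P(d) = γ + (1 − γ)(1 − exp(−Σⱼ βⱼdʲ)) with γ ∈ [0, 1), βⱼ ≥ 0. Binomial
maximum likelihood; doses are rescaled by the maximum dose internally so
the coefficients are O(0.1) and gradient-based optimization is well
conditioned. The start list is deterministic: a non-negative-least-squares
fit on the linearized cumulative-hazard scale plus a coarse parameter grid
(≥ 28 starts), each polished by L-BFGS-B, with a final Nelder-Mead polish —
no randomness anywhere in fitting. A dense-grid oracle test verifies the
optimizer is not beaten by more than 1e−3 log-likelihood units, and the
three-group dataset has an exact analytic (saturated) solution the fit must
match.

Degree is selected by minimum AIC over degrees 1..max_degree (default 2),
ties toward the lower degree, with successive likelihood-ratio tests (χ²,
1 df) reported alongside; all fitted parameters are counted in the AIC
whether or not they sit on a boundary. All three shipped bioassays select
degree 2.

BMD at benchmark response 0.10 solves the *extra-risk* equation
1 − exp(−Σ βⱼBʲ) = 0.10 (closed form for degree ≤ 2, polynomial root
otherwise). The BMDL profiles the likelihood: the constraint Σ θⱼB*ʲ = A
eliminates β₁, the inner 2-parameter maximization runs warm-started between
bisection steps, and bisection stops at 1e−6 relative width. The cutoff is
χ²₁(2·confidence − 1)/2 = 1.35277 at the default one-sided 95%. A test
verifies that re-maximizing with the BMD pinned at the returned BMDL
reproduces LL_max − 1.35277 to 1e−4 via an independent SLSQP check.

**Known discrepancy.** The published BMD/BMDL values are not recoverable
from the published counts under any maximum-likelihood convention we could
identify. The clearest case: the three-group dataset with a 3-parameter
degree-2 model is *saturated*, so the ML solution interpolates the observed
fractions exactly and the BMD is analytically determined — 1241.7 μg/m³,
not the published 1289.7 (the published BMDL 936.3 vs computed 888.4
similarly). Alternative conventions (unrounded doses, background fixed at
the control fraction, added-risk BMR, degrees 1/3, the narrative control-n)
were all probed and none reproduces the published values; the deviation
ratios are also inconsistent across the three datasets, pointing at
optimizer non-convergence in the original third-party software run rather
than a definable convention. The pipeline reports its own ML values,
flags each computed-vs-published deviation, and uses the published PODs
only where downstream published arithmetic is keyed to them.

## Linear low-dose extrapolation

The point-of-departure line passes through (0, control fraction) and
(BMDL, 0.10): intercept β₀ = control fraction, slope
β₁ = (0.10 − β₀)/BMDL, and RR(d) = (β₀ + β₁d)/β₀ at the ambient target,
default 65 μg/m³ (the 1997 24-hour fine-particle standard). The response
at the POD is the design value 0.10 itself, not γ + (1 − γ)·0.10 — that
literal reading reproduces the published RRs (1.426, 1.576) from the
published BMDLs and control fractions to 3 decimals. A zero control
fraction makes the RR undefined (division by β₀) and is rejected; so is a
control fraction at or above the BMR.

For the third bioassay no input combination reproduces the published RR:
the published BMDL (716.572) and control fraction (4/250) give 1.476, not
the published 1.246. The pipeline computes and reports 1.476 with a
discrepancy flag, while the published 1.246 (and its CI) remains the
fixture feeding the meta-analysis, since that is what the published pooled
rows were built from.

The extrapolation CIs are exogenous fixtures: their derivation is not
described in the source (they are symmetric on the RR scale), and they are
needed only as meta-analysis weights.

## Meta-analysis

Pooling is on the **linear RR scale**: SE = (CI width)/(2·1.96), fixed
weights wᵢ = 1/seᵢ², Q = Σwᵢ(xᵢ − μ̂)², DL
τ² = max(0, (Q − df)/(Σw − Σw²/Σw)), random weights 1/(seᵢ² + τ²), CI
half-width z/√(Σw) with z = 1.96 throughout. The linear scale is
established by back-calculation: it reproduces the published pooled
estimates and their symmetric CIs (1.365 [1.075–1.654] animal,
1.594 [1.086–2.101] human-adjusted, 1.492 [1.210–1.775] overall) to three
decimals, while log-scale pooling does not. A log-scale option exists but
is off by default. Inputs to the pooled rows are the published rounded
adjusted estimates (1.24, 1.88, 1.76, 1.426, 1.246, 1.576), as in the
published table's own input rows.

Two published cells do not reproduce and are excluded from hard checks,
with flags: the unadjusted human random pool (published 1.727/1.73;
linear-scale DL on the printed inputs gives 1.657) and, downstream of it,
the published "adjusted (1.49) < unadjusted (1.59)" ordering — computed
from the printed inputs the six-study pools give 1.493 (adjusted) vs 1.474
(unadjusted), because the unadjusted set is dominated by the high-weight
1.40 estimate and has a much smaller τ². The pipeline reports both numbers
and flags the ordering rather than asserting it.

## Synthetic-data generators

Three seeded generators mirror the structure each stage assumes, with the
study conditions as defaults where the source states them:

- **Cohorts**: binomial case counts at I₀ and I₀·RR_true, then
  non-differential reclassification at (Se, Sp); both the true and the
  misclassified 2×2 tables are returned so correction methods can be scored
  against truth. A flag marks expected cells below 1.
- **Bioassays**: per-group counts ~ Binomial(n, P(dose)) from known
  multistage parameters, so the generating model's analytic BMD is
  available for recovery tests.
- **Study sets**: effects ~ Normal(μ, τ² + seᵢ²) on the linear scale
  (consistent with linear-scale pooling), seᵢ uniform in a given range,
  CIs μ̂ᵢ ± 1.96·seᵢ; non-positive draws are redrawn with bounded retries.

Generators are pure functions of their spec (seed included). What they do
*not* emulate: latency and survival structure, covariate-driven
confounding, differential misclassification, or the original cohorts'
sampling designs — so passing recovery tests demonstrates the estimators'
internal consistency under the stated models, not robustness to violations
of them.

## Problem sizes and tolerances in the test suite

Misclassification properties run at 10,000 trials per scenario (the
published trial count); BMD recovery uses 10⁴ animals per group; DL τ²
recovery uses the median over 500 replicates of 20 studies; the BMDL
coverage check runs 200 seeded replicates at 300 animals per group with a
relaxed profile tolerance (1e−4), which resolves the coverage question
while keeping the profile computation cheap. Published-table comparisons
use ±1 unit in the last printed decimal for closed-form arithmetic, 0.1%
relative for the benchmark-dose stage, and 0.2% for pooled estimates;
optimizer-vs-oracle agreement is asserted at 1e−3 log-likelihood units and
the profile property at 1e−4.

## Limitations

- The pipeline inherits every structural assumption of its sources: rat
  lung-tumour relevance to humans, linearity below the POD, a single
  binary confounder, non-differential misclassification.
- The published benchmark-dose values, one extrapolated RR, and two pooled
  cells are not reproducible from the published inputs (details above);
  they are carried as flagged fixtures, not silently corrected.
- Extrapolation CIs are taken as data, so the animal meta-analysis weights
  are only as good as those published intervals.
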