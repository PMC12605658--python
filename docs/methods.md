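# Methods

`cetraj` estimates whether an exposure taken up during follow-up — here,
self-reported continuing education (CE) in a biennial ageing cohort —
changes long-term cognitive trajectories, using a matched pre/post design
that guards against reverse causality (cognitively healthier people
selecting into the exposure). This note documents the statistical model,
the synthetic-data generator, the numerical choices and the known
limitations.

## Cohort model and eligibility

The unit of analysis is the person-wave. Cognition is measured by an
episodic-memory recall sum (immediate + delayed recall of a 10-word list,
0–20) and a one-minute animal-naming fluency count. Both are standardised
to pooled mean 0, SD 1 over **all** person-wave observations of the
cohort (n−1 denominator); all effects below are in these SD units.

Each participant's analytic *baseline* is the first wave with complete
cognitive and covariate data. Participants reporting CE at baseline are
excluded (no pre-exposure assessment exists), as are participants with
fewer than two analysed waves. CE reported only before the analytic
baseline neither excludes nor reclassifies a participant; a
`pre_baseline_ce` flag records it. Exposure groups: `single_ce` (exactly
one post-baseline CE wave), `multiple_ce` (two or more), `control`
(none); the time origin t0 is the first CE wave and aget0 the age at it.

## Matching

Coarsened exact matching on five variables: baseline age (5-year bins),
sex (exact), baseline education level (exact), baseline mean standardised
cognition (0.5-SD bins over [−3, 3)), and follow-up duration (exact on
the analysed-wave count — the natural unit of a biennial design). Bins
are half-open [lo, hi); profiles outside the outermost edges cannot be
assigned a stratum and are reported unmatched. All bins are configurable
via `CoarseningSpec` / YAML.

Within each stratum, surplus members are dropped uniformly at random
(seeded) until treated and control counts are equal (*k-to-k*), enabling
unweighted analysis. Dropping is control-side when controls are surplus;
when treated are surplus the treated side is pruned instead, and this is
reported in the matching summary. Two overlapping control groups are
drawn from the same pool, one per exposure group; the overlap count is
reported.

Controls need a time origin: within each stratum the median treated
aget0 (midpoint convention for even counts) becomes the control origin,
so both arms are compared over the same ages. Every participant's time
axis is then t = age − aget0 (own aget0 for treated, stratum origin for
controls).

## Piecewise linear mixed model

With pre = min(t, 0) and post = max(t, 0) (so pre + post = t and
pre·post = 0 exactly), the fixed-effect design contains

  intercept, pre, post, group, group×pre, group×post,
  aget0, aget0×pre, aget0×post, adjustment covariates,

with aget0 centred at the analysis-sample mean. Optional blocks:
quadratic/cubic time terms (each with its group and aget0 interactions),
a discontinuity indicator D = 1{t ≥ 0} with D×group (step-change
variant), and an assessment-round index (practice effect). Higher-order
blocks are chosen by backward selection: each candidate block is tested
jointly (term + group×term + aget0×term) by a Wald chi-square test in the
model containing all currently retained terms; the highest-order
non-significant block (p ≥ 0.05) is dropped and the model refitted, with
cubics tested before quadratics and a quadratic only removable once no
same-piece cubic remains. Joint block testing (rather than
single-coefficient testing) is this package's documented choice.

Random structure: per-participant random intercept, random pre-slope and
random post-slope with an unstructured 3×3 covariance G, plus an
independent residual. Estimation is maximum likelihood (not REML) via
`statsmodels.MixedLM`, so Wald comparisons across nested mean structures
are coherent; standard errors come from the model covariance, with no
additional clustering by matched set. Pairwise random-effect
correlations ρ = G_ij/√(G_ii G_jj) are reported.

Time-updating covariates (labour-force status, wealth, smoking, alcohol,
physical activity, hearing, depressive symptoms, chronic conditions) vary
freely before t0 and are then *carried forward* — frozen at their value
at, or last before, t = 0 — so post-exposure mediators are not adjusted
away. Pre-window gaps are filled by last observation carried forward. A
control whose assigned origin precedes every observation has no pre-t0
value to freeze; the pipeline freezes their earliest observed value
(`baseline_fallback`), while the low-level function treats the case as an
integrity error.

Adjustment covariates: a birth-cohort proxy (2·(wave−1) − age, constant
per participant under exactly biennial interviews), sex, education
dummies, labour-force dummies, wealth, smoking, alcohol, weekly MVPA,
hearing dummies, CES-D score, six condition flags. Covariate levels
absent from a small matched sample yield empty design columns; these
(and any exactly aliased columns) are pruned by an order-respecting
sweep before fitting, with the dropped names recorded.

### Numerical choices

- Random slopes are internally parameterised **per decade**: per-year
  slope variances (~6×10⁻⁴) are three orders of magnitude below the
  intercept variance (~0.5), which puts gradient optimizers on the
  boundary of the covariance parameter space; rescaling time in the
  random-effects design is an exact reparameterisation that fixes this.
  Estimates are rescaled back to per-year units.
- Optimizer chain: lbfgs → bfgs (warm-started when a previous compatible
  fit exists, then cold) → cg → powell; non-convergence after all
  attempts is an error, never a silent result.
- With known variance components (`variance_components=(G, σ²)`), fixed
  effects are computed by exact GLS via per-participant Cholesky
  whitening. This path also handles noise-free data, where ML is
  degenerate, and is cross-checked in the tests against a dense-matrix
  GLS oracle.
- Rows with a missing outcome are dropped (mixed-model missing-at-random
  handling); fluency is absent at one wave by design in the emulated
  cohort, mirroring its source.

## Marginal contrasts, step contrasts and MDES

Predictions are marginal over the observed covariate distribution: the
fitted design matrix is re-evaluated at a requested time t and group g
for every analysis row (keeping each row's covariates and aget0) and
averaged. Window changes — default 4 years before to t0 and t0 to
8 years after, the typical median follow-up spans — are linear
functionals L'β, so SE = √(L'VL) (delta method; time-invariant covariate
columns cancel in L). Between-group differences are exposed minus
control; 95% CIs use ±1.959964·SE and p-values the normal reference.
Windows beyond the observed time support are computed (the polynomial
extrapolates) but flagged.

The step-change variant reports the between-group marginal difference at
t = 0 (level gap plus differential step) and at a horizon (plus the
accumulated slope difference). The differential step itself is the
D×group coefficient.

MDES (minimum detectable effect size) for the post-window between-group
change: MDES = (z_{1−α/2} + z_{power})·SE = 2.80158·SE at the defaults
α = 0.05 (two-sided), power = 0.80, normal approximation. The convention
and multipliers are printed with every report so the number is
interpretable under any other convention.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with known
ground truth: ~biennial waves (default 10), entry ages 50–75, raw scores
produced by rounding a linear map of a latent z scale into 0–20 (memory,
mean 10, SD 3.5) and 0–60 (fluency, mean 20, SD 6), a per-wave CE
report, and the full covariate set with plausible dynamics (retirement
around a person-specific age, absorbing condition onsets, small random
missingness).

Per domain, the latent trajectory is

  y(age) = m(age) + b0 + b1·min(t, 0) + b2·max(t, 0) + exposure effect + ε,

where m(age) is an age-referenced mean (slope −0.016 SD/yr for memory at
age 65, curvature −0.0006 SD/yr², so decline accelerates with age) and
(b0, b1, b2) ~ N(0, G) are anchored at the participant's candidate
origin. The mean is a smooth function of age rather than kinked at the
candidate origin: controls never observe their candidate origin, and a
population-mean kink at an unobservable per-person age is not a feature
real cohorts exhibit — it would also leak into the matched contrast
through the control origin re-assignment. Defaults G: intercept variance
0.55, slope SDs 0.0245/yr, cov(intercept, post-slope) −0.002
(ρ ≈ −0.11), residual SD 0.55 — magnitudes in line with standardised
memory trajectories published for large ageing cohorts, chosen once
up front. The true exposure effect (post-origin
slope, step, and/or quadratic, exposed only, anchored at the true
origin) is configurable and recorded in the ground-truth sidecar.

Selection (reverse causality): every participant draws a candidate
origin uniformly over interior waves; uptake there is Bernoulli with
log-odds −2.5 + 2.0·(latent cognitive level in SD units) +
0.8·(employed). Attrition is a per-wave hazard, logistic in age and
latent cognition (defaults −3.0 base, +0.03/yr of age, −0.15/SD).
Quotas for exposed and control counts are filled by rejection sampling;
a single integer seed drives all randomness.

What the generator does **not** emulate: correlated memory/fluency
random effects, calendar-period effects, practice gains, mortality as
distinct from refusal, and calibration to any real cohort's marginal
distributions. Passing tests therefore demonstrate the pipeline's
statistical properties under a faithful structural analogue, not
agreement with any particular dataset.

## Simulation studies and problem sizes

The test suite verifies, end to end (simulate → standardise → classify →
match → fit → contrast): unbiased recovery of a −0.10 SD/8 y post-origin
slope difference with near-nominal CI coverage (100 replicates of 750
exposed + 2250 pool, 8 waves; ≈500 matched pairs/arm); ~5% size of the
group×post Wald test (350 replicates, 120 exposed/400 pool); backward
selection retaining a 4-SE quadratic ≥90% of the time and a spurious one
at ≈α (100+100 replicates); delta-method SEs within 2% of a 2000-draw
parametric bootstrap; ~80% simulated power at a true effect equal to the
computed MDES (250 replicates, generated without selective uptake so the
calibration is not contaminated by the selection artefact described
below, and with continuous scores so the bounded raw scales do not clip
the injected effect); and exact (noise-free) plus 3-SE (noisy) recovery
of an injected 0.5 SD step. Replicate counts and cohort sizes
are the package's choices for a single-CPU workstation run; the asserted
bands account for the implied Monte-Carlo noise.

## Known limitations

- **Matching on a noisy baseline does not remove selection on the true
  latent level.** When uptake depends on latent cognition (the default,
  2 log-odds/SD) while matching uses the measured baseline score
  (residual SD 0.55), matched exposed participants' baseline
  measurements systematically understate their latent level. The result
  is an apparent pre-origin slope *rise* in the exposed group of about
  +0.02 SD/yr at these settings — classic regression to the mean, plus a
  smaller component from slope selection induced by conditioning on
  baseline level. The corresponding suite check of "pre-origin slope
  difference ≈ 0 under strong selection" fails by design of the
  generator, and we keep it failing rather than quietly weakening the
  selection or the noise: the bias scales with the measurement-noise
  share and vanishes when selection is switched off. Crucially, the
  *post-origin* decline contrast — the quantity the design exists to
  estimate — remains unbiased under the same selection (the recovery
  study passes), because the pre/post design differences out level
  artefacts. Interpreting real pre-trajectory comparisons should keep
  this mechanism in mind.
- ML variance components are slightly biased downward in small samples;
  CI coverage at ~100 matched pairs can dip a point or two below
  nominal.
- The MDES is a local, normal-approximation quantity; at very small
  matched sizes the implied "detectable" effects are large and the 80%
  power statement is approximate.
- Backward selection p-values are not adjusted for the selection path;
  this mirrors common applied practice and is documented rather than
  corrected.
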