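# cetraj — matched pre/post trajectory analysis of cognitive decline

Does taking up an activity in mid-to-late life — here, self-reported
continuing education (CE) in a biennial ageing cohort — bend long-term
memory and verbal-fluency trajectories? Naive comparisons are confounded
by reverse causality: cognitively healthier people are the ones who
enrol. `cetraj` implements the matched longitudinal design that
addresses this, for epidemiologists and biostatisticians who work with
long-format panel data on cognition:

1. **Cohort handling** — long-format CSV I/O, pooled z-standardisation
   of raw scores, analytic-baseline and eligibility rules, exposure
   classification into single vs. multiple CE reporters.
2. **Coarsened exact matching (CEM) with k-to-k pruning** — strata from
   binned baseline age, sex, education, baseline mean cognition and
   follow-up duration; surplus stratum members dropped uniformly at
   random so the arms are equal and no model weights are needed. Two
   overlapping control groups are drawn from one pool.
3. **Time-origin alignment** — t = 0 at each exposed participant's first
   CE report; controls inherit their stratum's median age-at-exposure as
   origin so both arms are compared over the same ages.
4. **Piecewise linear mixed models** — for person i at time t,

       y_it = Xβ + b0_i + b1_i·min(t,0) + b2_i·max(t,0) + ε_it,
       (b0, b1, b2) ~ N(0, G) unstructured, ε ~ N(0, σ²),

   fitted by maximum likelihood, with group×time and aget0×time
   interactions, Wald backward selection of quadratic/cubic time terms,
   carry-forward of time-updating covariates after t0, and an optional
   step-change (discontinuity) variant.
5. **Marginal inference** — predicted trajectories averaged over the
   observed covariate distribution, 4-year-pre / 8-year-post decline
   contrasts with delta-method CIs, step contrasts, and the minimum
   detectable effect size, MDES = (z_{1−α/2} + z_{power})·SE.
6. **Synthetic cohorts** — a generator with latent random
   intercept/slope trajectories, selective CE uptake (reverse
   causality), attrition and known ground truth, so the entire pipeline
   is testable without access to any real cohort.

Core classes follow scikit-learn conventions (`fit`, trailing-underscore
attributes, `get_params`): `ScoreStandardizer`, `CoarsenedExactMatcher`,
`PiecewiseLinearMixedModel`; plain functions wrap them for script use.

## Worked example

Simulate a cohort under the default study conditions (selective uptake,
no true effect of CE) and run both matched analyses end to end:

```bash
cetraj run --seed 7 --config examples/run.yaml --out-dir out/
cetraj contrast --cohort out/cohort.csv --config examples/run.yaml \
    --seed 7 --group single_ce --outcome memory_z --out-dir out_contrast/
```

with `examples/run.yaml`:

```yaml
simulation: {n_exposed: 400, n_control_pool: 1200, n_waves: 8}
outcomes: [memory_z]
candidate_terms: [post2]
```

The contrast command prints

```
single_ce/memory_z: post-window difference -0.193 SD (95% CI -0.414 to +0.029), MDES 0.316 SD
```

Reading: over the eight years after first reporting continuing
education, the matched CE group's memory declined 0.193 SD *more* than
its matched controls. The simulated truth is "no effect", and the 95%
CI duly includes zero — at this small matched size (97 pairs) a
1.7-SE draw under the null is unremarkable, and the MDES makes the
resolution explicit: only a true 8-year difference of at least 0.32 SD
would be detectable here (two-sided α = 0.05, power 0.80). The MDES
shrinks roughly with √n of the matched sample.
`out/summary.json` carries the full report: exclusion ledger, matching
summaries with the control-overlap count, balance table (standardised
mean differences; exactly-matched variables are exactly 0), fitted
fixed effects, the random-effects covariance G with its correlations ρ,
selection trail, contrasts, and `trajectories_*.svg` plots of the
marginal curves over t ∈ [−4, 8].

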