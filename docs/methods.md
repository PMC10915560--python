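# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `ptdkit`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The hierarchical discounting model

Per valence, affect intensity is a quadratic function of time distance with
nested random effects:

    A_ijt = (b0 + u0_i + e_ij) + (b1 + u1_i) t + (b2 + u2_i) t²+ ε_ijt,
    u_i ~ N(0, Σ_u),   e_ij ~ N(0, σ_e²),   ε ~ N(0, σ²).

Design choices and their reasons:

- **Raw day units.** Time is never centred or rescaled, so the intercept is
  the affect intensity at the moment of the event and the slope is in affect
  units per day. This makes intercepts near ±50–70 directly interpretable on
  the −100..100 visual-analog scale.
- **Participant slopes, event intercepts.** Individual discounting-rate
  scores require participant-level linear and quadratic deviations. Events
  contribute only intercept deviations by default: eight observations per
  event cannot support event-level slopes robustly. (Event-level structure
  beyond intercepts is deliberately not offered; the participant covariance
  is fully free.)
- **Two separate models.** Positive and negative valences are fitted
  independently; nothing ties their parameters except the generator's
  cross-valence coupling (below).
- **Quadratic by default, cubic exposed.** `MCMCConfig(degree=3)` exists for
  completeness but is unsupported: higher-degree trajectories are poorly
  identified at 8 waves and tend to fail the convergence gate, which is the
  intended behaviour (the gate raises rather than returning a silently bad
  fit).

### Sampler

Every conditional of this Gaussian hierarchy is conjugate, so the posterior
is drawn with a blocked Gibbs sampler. Two parameterization choices matter
far more than the sweep count:

- Participant deviations are written `u_i = Λ w_i` with `w_i ~ N(0, I)` and
  `Λ` lower-triangular (`Σ_u = ΛΛᵀ`); event deviations as `e_ij = λ_e h_ij`
  with `h ~ N(0, 1)`. Given the latent coordinates, all scale parameters
  enter the mean linearly, so `(β, Λ, λ_e)` are drawn together as a single
  conjugate Gaussian regression block.
- Centered alternatives (inverse-Wishart given `u`, inverse-gamma given `e`)
  were tried first and mix an order of magnitude worse when a deviation SD
  is small relative to its sampling noise — the classic funnel. The
  Cholesky-factor expansion lets the data move every scale directly each
  sweep and cut the worst autocorrelation time from roughly 200 sweeps to
  roughly 75 on the reference design.

**Priors** are weakly informative and scale-adapted: fixed effects and the
free elements of `Λ` and `λ_e` are `N(0, (10·sd(y))²)` — implying
half-Gaussian-tail margins on all deviation SDs and near-uniform margins on
the correlations — and the residual SD has a half-Student-t(3, sd(y)) prior
via the standard inverse-gamma mixture. The regression-block prior is what
makes the expansion conjugate; the test suite verifies that doubling all
prior scales moves the fixed-effect posterior means by well under 5%, which
is the property that actually matters at these data sizes.

**Defaults: 4 chains × 45000 sweeps, 3000 warm-up, keeping every 15th
draw.** A Gibbs sweep costs ~1 ms on the reference design (~2.5 min per
model) but is less effective per iteration than a gradient-based transition
for the weakly identified deviation SDs; this length clears R-hat < 1.01 on
every reported parameter and bulk-ESS > 1000 on the trajectory coefficients.
The classic 4 × 4000 protocol can be configured but will generally warn on
the deviation-SD diagnostics under this sampler. Convergence contract:
R-hat ≥ 1.05 on any reported parameter raises `ConvergenceError`;
R-hat ≥ 1.01 or bulk-ESS ≤ 1000 warns.

**HPDI.** The highest-posterior-density interval is computed by the
shortest-window search over the sorted sample — exact for the unimodal
marginals this model produces, and cross-checked against `arviz.hdi` and a
brute-force O(n²) search in the tests.

**Posterior predictive check.** The distance between the observed and a
replicated dataset is the largest Kolmogorov–Smirnov statistic across
time-distance quartile bins (a pooled KS alone has almost no power against
trajectory-shape misfit, since it ignores time). The verdict compares the
median observed-vs-replicate distance with the replicate-vs-replicate
distance distribution.

**Degenerate inputs.** Variances are floored at 1e-6 (squared affect units)
so exactly-polynomial data (zero noise) cannot break the conjugate updates;
this floor is far below any measurable rating noise.

## Discounting-rate scores

Individual paths are the posterior-mean fixed effects plus each
participant's posterior-mean deviations (event deviations average out). A
per-draw mode (AUC per posterior draw, then averaged) is available via
`score_cohort(..., method="per_draw")`; the extract-then-predict default is
the primary, documented path.

Scaling and AUC: predictions on integer days 4..63 (60 points); time mapped
to [0, 1] by `(t − 4)/59`; affect divided by its first predicted value
(negative-valence curves become positive automatically — no absolute values
anywhere); composite trapezoid rule. The closed-form integral of the scaled
quadratic serves as an oracle: the trapezoid error is bounded by
`|b2| / (6 |v(4)|)` on this grid, i.e. below 2e-4 for any curve whose
initial intensity is not vanishingly small. Participants with a negative
AUC in either valence are excluded (a negative area contradicts the
definition of a discounting rate); a configurable screen can additionally
flag participants whose wave-mean rating sign contradicts the event valence
in at least half the waves (off by default — the synthetic generator does
not produce such raters, and the screen is a stand-in for richer
plausibility checks on real data).

**PTD bias** is normalized AUC-positive minus normalized AUC-negative over
included participants; normalization is z-scoring by default (min–max via
config). Positive bias = negative events discount faster.

## Inference

- Paired comparison of the two AUCs: t statistic on differences with a
  sign-flip permutation null (the natural exchangeability for paired data),
  two-sided, add-one correction so p is never exactly 0. Effect size is
  d_z = t/√n, the paired-design convention (mean difference over the SD of
  differences). Identical pairs return t = 0, p = 1; a constant non-zero
  difference raises (the statistic is undefined).
- Spearman correlation with a permutation null (y permuted), average ranks
  for ties.
- Standardized regressions: outcome and both predictors z-scored, OLS,
  normal-theory 95% CIs. The two-predictor correlation-form closed form is
  the oracle in the tests.
- No multiple-testing correction across the five outcomes; the results
  table carries a note saying so.
- Power simulation: simulate → refit with a fast frequentist refitter
  (per-participant pooled OLS quadratic fits, one-sample t-test of the
  linear coefficients across participants) → count rejections;
  Clopper–Pearson binomial CI. The refitter tests the same null (no mean
  linear trend) as the Bayesian fixed effect and is orders of magnitude
  faster, which is what makes hundreds of replicates feasible.

## The synthetic-cohort generator

The generator emulates the study design: events uniformly dated within the
31 days before baseline, encoding intensity truncated-normal(65, 15) on
[35, 100] (a floor of 35 guarantees recalling the event still arouses
measurable affect), 8 waves every 4 days, time distances 4–63 days. Ratings
are the event-level true path plus Gaussian noise, clipped to the VAS bounds
with the clip count logged (clip-and-log was chosen over truncated sampling
for transparency; the clipped fraction at defaults is under 1%).

Generating parameters:

| parameter | default | note |
|---|---|---|
| fixed effects, positive | (67.806, −0.816, 0.007) | population trajectory |
| fixed effects, negative | (−51.569, 0.683, −0.006) | population trajectory |
| participant deviation SDs | (10, 0.15, 0.002) | affect units, units/day, units/day² |
| participant deviation correlations | identity | configurable 3×3 |
| cross-valence coupling | 0.4 | intensity scale, see below |
| event intercept SD | 8 | affect units |
| residual SD | 12 | affect units |

The deviation, event and residual SDs are design choices, not estimates —
chosen so simulated spaghetti plots show a realistic spread of trajectories
around the population curves; they are documented as unvalidated against
any real cohort.

**Cross-valence coupling** correlates affect *intensity* across valences: a
participant who feels positive events strongly also feels negative events
strongly (i.e. `corr(u0_pos, −u0_neg) = +0.4`). On the raw intercept scale
this is a negative correlation, because negative-event intercepts point
down. This sign convention is what makes the two AUC rates positively
correlated downstream, matching the empirically observed positive
association between the two discounting rates.

**Scale scores.** Latent score = `γ_pos·z(AUC_pos) + γ_neg·z(AUC_neg) +
noise`, with noise variance `1 − γ_pos² − γ_neg²` so the latent is
approximately unit-variance; mapped affinely into the instrument range
(centre = midpoint, SD = one sixth of the range), rounded, clipped. Default
γ pairs follow the fading-affect-bias pattern: well-being loads positively
on AUC-positive and negatively on AUC-negative; the four distress scales
mirror it.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: dropout and missed waves (completers only),
floor/ceiling response styles and anchoring, integer-grid or coarse VAS
responding, affect that changes sign systematically (sign flips arise only
through noise), event-specific slopes, non-Gaussian heavy-tailed rating
noise, and any real covariance between questionnaire subscales beyond the
single latent link.

## Problem sizes used in the checks

Parameter recovery is checked on one full-size cohort (210 participants;
both valences, default sampler length) plus twenty reduced cohorts (40
participants, shorter chains) for HPDI coverage; the calibration studies
use hundreds of small permutation tests. The acceptance script refits the
full-size design once per valence. These sizes keep a complete run in the
tens of minutes on a single CPU while leaving every check at its stated
tolerance.

## Known limitations

- The sampler is specialized to the Gaussian quadratic hierarchy; swapping
  likelihoods or adding covariates means writing new conditionals (by
  design — the contract is the diagnostics, not sampler generality).
- Weakly identified deviation SDs (the quadratic component especially) have
  wide, boundary-adjacent posteriors at small cohort sizes; their ESS is
  the binding constraint on run length.
- AUC scoring assumes the quadratic path; the per-draw mode propagates
  posterior uncertainty into the score but the default does not (scores are
  point summaries, as in the extract-then-predict tradition).
- The abnormal-pattern screen is a plausibility stand-in, not a validated
  artifact detector.
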