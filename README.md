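# ptdkit

Tools for studying **past temporal discounting (PTD)** — the decline, over
elapsed time, of the affect intensity people feel when recalling a past
event — and its relationship to mental health. The happiness of recalling a
vacation and the sting of recalling a failed exam both fade; they fade at
different rates, and the balance of those rates (the *fading affect bias*)
appears to matter for well-being.

`ptdkit` is aimed at researchers running longitudinal affect-recall designs:
each participant recalls a fixed set of positive and negative recent events
and re-rates the affect each recall elicits (visual-analog scale, −100..100)
at regular follow-up waves. Because such datasets are rarely shareable, the
package includes a first-class synthetic-cohort generator that emulates the
design (210 participants, 3 events per valence from the past month, 8 waves
every 4 days, time distances 4–63 days), so the entire pipeline is testable
end to end without any data download.

## The model and the discounting score

Affect intensity for event *j* of participant *i* at time distance *t* days
is modelled per valence with a Bayesian mixed-effects quadratic model,

```
A_ijt = (b0 + u0_i + e_ij) + (b1 + u1_i)·t + (b2 + u2_i)·t² + ε_ijt
```

with participant-level deviations `u_i ~ N(0, Σ_u)` (intercept, linear,
quadratic, freely correlated), event-within-participant intercept deviations
`e_ij ~ N(0, σ_e²)`, and Gaussian residuals. Time enters in raw days, so
`b0` is affect at the moment of the event. The posterior is sampled with a
conjugate blocked Gibbs sampler in a Cholesky-factor parameterization (see
`docs/methods.md`), with rank-normalized split R-hat and bulk-ESS
diagnostics; a fit with any R-hat ≥ 1.05 raises an error.

Each participant's discounting rate is summarized by the **area under their
scaled recall curve**: the individual path (posterior-mean fixed effects plus
that participant's posterior-mean deviations) is evaluated on integer days
4..63, time is mapped to [0, 1] via `(t − 4)/59`, affect is divided by its
first predicted value so every curve starts at (0, 1), and the AUC is taken
by the trapezoid rule (a closed-form quadratic integral is provided as an
oracle). AUC = 1 means no discounting; smaller means faster discounting;
negative AUCs violate the definition and exclude the participant.

The inferential battery mirrors the field's practice: a paired sign-flip
permutation test comparing AUC-positive with AUC-negative (effect size
d_z = t/√n), a permutation Spearman correlation between the two rates,
standardized regressions of five mental-health questionnaire totals
(WEMWBS, BDI, TAI, PSS, RRS) on both AUCs, permutation correlations of the
**PTD bias** (normalized AUC-positive minus normalized AUC-negative) with
each scale, and a Monte-Carlo design power simulation.

## Worked example

```python
import ptdkit as pk

cohort = pk.simulate_cohort(pk.CohortConfig(seed=7))      # 210 x 6 x 8 ratings
mcmc = pk.MCMCConfig(n_iterations=8000, n_warmup=1000, thin=4, seed=3)
fit_pos = pk.fit_discount_model(cohort.panel, 1, mcmc)
fit_neg = pk.fit_discount_model(cohort.panel, -1, mcmc)
print(fit_pos.summary.loc[["Intercept", "Time", "Time^2"]].round(3))

records = pk.score_cohort(fit_pos, fit_neg)
included = records[records["included"]]
print(f"AUC-positive: M = {included.auc_pos.mean():.3f}, SD = {included.auc_pos.std():.3f}")
print(f"AUC-negative: M = {included.auc_neg.mean():.3f}, SD = {included.auc_neg.std():.3f}")

test = pk.paired_permutation_test(included.auc_pos.to_numpy(),
                                  included.auc_neg.to_numpy(), seed=1)
print(f"paired t = {test.statistic:.2f}, permutation p = {test.permutation_p:.3f}, "
      f"d_z = {test.effect_size_d:.3f}")

results = pk.run_mental_health_models(records, cohort.scales, seed=2)
print(results[(results.analysis == "regression")
              & (results.outcome == "wemwbs")].round(3).to_string(index=False))
```

prints

```
           estimate  hpdi_low  hpdi_high   rhat  ess_bulk
parameter
Intercept    69.203    66.590     71.799  1.005  1127.712
Time         -0.827    -0.952     -0.698  1.001  6217.976
Time^2        0.007     0.005      0.009  1.001  6414.679
AUC-positive: M = 0.773, SD = 0.070
AUC-negative: M = 0.759, SD = 0.086
paired t = 1.99, permutation p = 0.063, d_z = 0.137
  analysis outcome    term  estimate  ci_low  ci_high     p   n
regression  wemwbs auc_pos     0.279   0.143    0.415 0.000 210
regression  wemwbs auc_neg    -0.182  -0.318   -0.046 0.009 210
```

Reading this: the cohort was generated with population coefficients
(67.806, −0.816, 0.007) for positive events, and the fit recovers them
inside the 95% HPDIs — affect declines by ~0.8 points/day at first, the
positive quadratic term flattening the decline with distance. Mean
AUC-positive 0.773 exceeds mean AUC-negative 0.759: positive-event affect
is retained slightly better, the fading-affect-bias direction. The
well-being regression recovers the generating standardized effects (+0.284
on AUC-positive, −0.133 on AUC-negative) within their CIs: slower
discounting of positive events and faster discounting of negative events
both go with higher well-being. (The sampler may log warnings for
weakly-identified deviation SDs at these reduced draw counts; the fixed
effects are unaffected.)

A command-line front end wraps the same stages:

```bash
ptdkit simulate -c config.yaml        # write a synthetic cohort
ptdkit run -c config.yaml             # full pipeline: simulate/fit/score/analyze
ptdkit power -c config.yaml --n-participants 210 --n-sims 200
```

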