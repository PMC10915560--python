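"""Inferential battery linking discounting rates to mental health.

Comprises: a paired permutation test comparing AUC-positive with
AUC-negative (sign-flips of paired differences, two-sided, add-one
correction so p is never exactly 0), a permutation Spearman correlation,
standardized two-predictor regressions of each mental-health total on
AUC-positive and AUC-negative, permutation Spearman correlations of the PTD
bias with each scale, and a Monte-Carlo design power simulation using a fast
frequentist refitter (per-participant OLS quadratic fits plus a one-sample
t-test on the linear coefficients).

The paired effect size uses the d_z convention, d = t / sqrt(n) (mean
difference divided by the SD of differences).  No multiple-testing
correction is applied across the five outcomes; results report per-outcome
p-values and the tidy table carries a note saying so.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger("ptdkit.inference")

__all__ = [
    "PermutationTestResult",
    "RegressionReport",
    "PowerResult",
    "paired_permutation_test",
    "spearman_permutation",
    "standardized_regression",
    "run_mental_health_models",
    "power_simulation",
    "SCALE_ORDER",
]

SCALE_ORDER = ["wemwbs", "bdi", "tai", "pss", "rrs"]

MULTIPLE_TESTING_NOTE = (
    "p-values are per-outcome; no multiple-testing correction applied")


@dataclass
class PermutationTestResult:
    statistic: float          # t (paired test) or rho (correlation)
    permutation_p: float
    n_permutations: int
    n: int
    effect_size_d: float | None = None
    seed: int | None = None


@dataclass
class RegressionReport:
    outcome: str
    coefficients: pd.DataFrame  # index: predictor; beta, ci_low, ci_high, p
    n: int


@dataclass
class PowerResult:
    target: str
    n_simulations: int
    alpha: float
    power: float
    ci_low: float
    ci_high: float
    config: dict = field(default_factory=dict)


def _perm_p(null_stats: np.ndarray, observed: float) -> float:
    """Two-sided permutation p with add-one correction (never exactly 0)."""
    return (np.sum(np.abs(null_stats) >= abs(observed)) + 1.0) / \
        (len(null_stats) + 1.0)


def paired_permutation_test(x, y, n_perm: int = 1000, seed: int = 0
                            ) -> PermutationTestResult:
    """Paired t statistic on x - y with a sign-flip permutation null.

    Cohen's d is the paired-design d_z = t / sqrt(n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            # identical pairs carry no evidence either way
            return PermutationTestResult(0.0, 1.0, n_perm, n,
                                         effect_size_d=0.0, seed=seed)
        raise ValueError("zero variance of paired differences; t undefined")
    t_obs = diff.mean() / (sd / np.sqrt(n))
    d = t_obs / np.sqrt(n)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    flipped = signs * diff[None, :]
    sds = flipped.std(axis=1, ddof=1)
    sds[sds == 0] = np.inf
    t_null = flipped.mean(axis=1) / (sds / np.sqrt(n))
    p = _perm_p(t_null, t_obs)
    return PermutationTestResult(float(t_obs), float(p), n_perm, n,
                                 effect_size_d=float(d), seed=seed)


def spearman_permutation(x, y, n_perm: int = 1000, seed: int = 0
                         ) -> PermutationTestResult:
    """Spearman rank correlation with a permutation null (y permuted).

    Ties get average ranks; rho is the Pearson correlation of the ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input; rank correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    rho = float(zx @ zy / n)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = zx @ zy[rng.permutation(n)] / n
    p = _perm_p(null, rho)
    return PermutationTestResult(rho, float(p), n_perm, n, seed=seed)


def standardized_regression(outcome, predictors: pd.DataFrame,
                            outcome_name: str = "outcome") -> RegressionReport:
    """OLS of the z-scored outcome on z-scored predictors.

    Coefficients are therefore standardized betas, reported with their 95%
    confidence intervals and two-sided p-values.  Complete cases only.
    """
    y = pd.Series(np.asarray(outcome, dtype=float))
    Xf = predictors.reset_index(drop=True).astype(float)
    mask = y.notna() & Xf.notna().all(axis=1)
    y, Xf = y[mask], Xf[mask]
    n = len(y)
    if n <= 3:
        raise ValueError("need more than 3 complete cases")
    corr = Xf.corr().to_numpy()
    off = corr[~np.eye(len(corr), dtype=bool)]
    if off.size and np.any(np.abs(off) >= 1.0 - 1e-12):
        raise ValueError("predictors are perfectly collinear")

    def _z(v):
        return (v - v.mean()) / v.std(ddof=1)

    Z = sm.add_constant(Xf.apply(_z))
    res = sm.OLS(_z(y), Z).fit()
    ci = res.conf_int(alpha=0.05)
    coef = pd.DataFrame({
        "beta": res.params,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "p": res.pvalues,
    }).drop(index="const")
    return RegressionReport(outcome_name, coef, n)


def run_mental_health_models(auc_records: pd.DataFrame,
                             scale_scores: pd.DataFrame,
                             n_perm: int = 1000, seed: int = 0
                             ) -> pd.DataFrame:
    """Five standardized regressions (one per scale, predictors AUC-positive
    and AUC-negative) plus five permutation Spearman correlations of the PTD
    bias with each scale.  Excluded participants are dropped.

    Returns a tidy table: analysis, outcome, term, estimate, ci_low,
    ci_high, p, n (with a multiple-testing note attached in ``attrs``).
    """
    missing = [s for s in SCALE_ORDER if s not in scale_scores.columns]
    if missing:
        raise ValueError(f"scale scores missing columns: {missing}")
    data = auc_records[auc_records["included"]].merge(
        scale_scores, on="participant_id", how="inner")
    logger.info("mental-health models: %d included participants", len(data))

    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(SCALE_ORDER))]
    for scale, s_scale in zip(SCALE_ORDER, seeds):
        rep = standardized_regression(
            data[scale], data[["auc_pos", "auc_neg"]], outcome_name=scale)
        for term, c in rep.coefficients.iterrows():
            rows.append(("regression", scale, term, c["beta"], c["ci_low"],
                         c["ci_high"], c["p"], rep.n))
        corr = spearman_permutation(data["ptd_bias"].to_numpy(),
                                    data[scale].to_numpy(),
                                    n_perm=n_perm, seed=s_scale)
        rows.append(("bias_correlation", scale, "ptd_bias", corr.statistic,
                     np.nan, np.nan, corr.permutation_p, corr.n))
    table = pd.DataFrame(rows, columns=["analysis", "outcome", "term",
                                        "estimate", "ci_low", "ci_high",
                                        "p", "n"])
    table.attrs["note"] = MULTIPLE_TESTING_NOTE
    return table


# ---------------------------------------------------------------------------
# Design power simulation
# ---------------------------------------------------------------------------

def _participant_linear_slopes(panel: pd.DataFrame, valence: int
                               ) -> np.ndarray:
    """Linear coefficients of per-participant pooled OLS quadratic fits."""
    rows = panel[panel["valence"] == valence]
    pids, idx = np.unique(rows["participant_id"].to_numpy(),
                          return_inverse=True)
    t = rows["time_distance_days"].to_numpy(dtype=float)
    y = rows["affect_rating"].to_numpy(dtype=float)
    X = np.vander(t, 3, increasing=True)
    P = len(pids)
    XtX = np.zeros((P, 3, 3))
    np.add.at(XtX, idx, np.einsum("ni,nj->nij", X, X))
    Xty = np.stack([np.bincount(idx, X[:, k] * y, minlength=P)
                    for k in range(3)], axis=1)
    coef = np.linalg.solve(XtX + 1e-9 * np.eye(3)[None], Xty[:, :, None])
    return coef[:, 1, 0]


def power_simulation(config, n_participants: int, n_sims: int = 200,
                     alpha: float = 0.05, seed: int = 0
                     ) -> dict[str, PowerResult]:
    """Monte-Carlo power to detect the linear time effects at a given N.

    Each replicate simulates a cohort from ``config`` (a CohortConfig) with
    ``n_participants`` and refits with the fast frequentist refitter:
    per-participant OLS quadratic fits, then a one-sample t-test of the
    linear coefficients against zero.  Power per valence with Clopper-Pearson
    95% binomial CIs.
    """
    from dataclasses import replace

    from .cohort import simulate_cohort

    if n_sims < 20:
        raise ValueError("n_sims < 20 gives a meaningless binomial CI")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_sims)]
    hits = {1: 0, -1: 0}
    for s in seeds:
        cfg = replace(config, n_participants=n_participants, seed=s)
        data = simulate_cohort(cfg)
        for valence in (1, -1):
            slopes = _participant_linear_slopes(data.panel, valence)
            if slopes.std(ddof=1) == 0:
                continue
            p = stats.ttest_1samp(slopes, 0.0).pvalue
            hits[valence] += int(p < alpha)

    out = {}
    for valence, label in ((1, "linear_time_positive"),
                           (-1, "linear_time_negative")):
        k = hits[valence]
        ci = stats.binomtest(k, n_sims).proportion_ci(
            confidence_level=0.95, method="exact")
        out[label] = PowerResult(
            target=label, n_simulations=n_sims, alpha=alpha,
            power=k / n_sims, ci_low=float(ci.low), ci_high=float(ci.high),
            config={"n_participants": n_participants, "seed": seed})
    return out
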