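"""Hierarchical model: HPDI, sampler correctness, diagnostics, PPC, curves."""

import warnings

import arviz as az
import numpy as np
import pytest

from ptdkit import CohortConfig, MCMCConfig, fit_discount_model, simulate_cohort
from ptdkit.model import (convergence_diagnostics, hpdi,
                          marginal_effect_curve, posterior_predictive_check,
                          predict_unobserved_participants, rhat_ess)
from ptdkit.scoring import QuadraticPath
from conftest import REDUCED_MCMC, make_point_mass_fit


# ---------------------------------------------------------------------------
# HPDI
# ---------------------------------------------------------------------------

def _hpdi_bruteforce(draws, prob):
    """O(n^2) shortest-window search, the defining computation."""
    s = np.sort(np.asarray(draws, float))
    n = len(s)
    m = int(np.ceil(prob * n))
    best = (np.inf, None)
    for i in range(n - m + 1):
        width = s[i + m - 1] - s[i]
        if width < best[0]:
            best = (width, (s[i], s[i + m - 1]))
    return best[1]


def test_hpdi_edge_cases():
    assert hpdi(np.full(10, 3.2)) == (3.2, 3.2)
    x = np.array([5.0, 1.0, 2.0, 9.0])
    assert hpdi(x, prob=1.0) == (1.0, 9.0)
    with pytest.raises(ValueError):
        hpdi([])
    with pytest.raises(ValueError):
        hpdi([1.0, 2.0], prob=1.5)


def test_hpdi_standard_normal():
    rng = np.random.default_rng(0)
    lo, hi = hpdi(rng.standard_normal(1_000_000), 0.95)
    assert lo == pytest.approx(-1.96, abs=0.02)
    assert hi == pytest.approx(1.96, abs=0.02)


@pytest.mark.parametrize("prob", [0.5, 0.8, 0.95])
def test_hpdi_matches_bruteforce_and_arviz(prob):
    rng = np.random.default_rng(7)
    for sample in (rng.standard_normal(400), rng.gamma(2.0, 1.0, 501),
                   rng.uniform(size=97)):
        assert hpdi(sample, prob) == _hpdi_bruteforce(sample, prob)
    # arviz's HDI is the independent cross-check (same definition, large n)
    sample = rng.gamma(3.0, 2.0, 20000)
    ours = hpdi(sample, 0.94)
    theirs = az.hdi(sample, hdi_prob=0.94)
    assert ours[0] == pytest.approx(theirs[0], abs=0.05)
    assert ours[1] == pytest.approx(theirs[1], abs=0.05)


# ---------------------------------------------------------------------------
# Sampler correctness
# ---------------------------------------------------------------------------

def test_noise_free_panel_recovers_fixed_effects_exactly():
    cfg = CohortConfig(n_participants=8, re_sd_participant=(0, 0, 0),
                       cross_valence_corr=0.0, re_sd_event_intercept=0.0,
                       residual_sd=0.0, seed=19)
    data = simulate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_discount_model(
            data.panel, 1,
            MCMCConfig(n_iterations=1500, n_warmup=500, thin=1, seed=1))
    beta = fit.fixed_effect_means()
    truth = np.array([67.806, -0.816, 0.007])
    np.testing.assert_allclose(beta, truth, rtol=1e-3)


def test_posterior_matches_pooled_ols_without_random_effects():
    """When the generator has no participant or event deviations, the fixed
    effects' posterior means sit on the pooled OLS quadratic (normal
    equations oracle), within 2 posterior SDs."""
    cfg = CohortConfig(n_participants=30, re_sd_participant=(0, 0, 0),
                       cross_valence_corr=0.0, re_sd_event_intercept=0.0,
                       residual_sd=12.0, seed=37)
    data = simulate_cohort(cfg)
    rows = data.panel[data.panel["valence"] == 1]
    t = rows["time_distance_days"].to_numpy(float)
    X = np.vander(t, 3, increasing=True)
    y = rows["affect_rating"].to_numpy(float)
    ols = np.linalg.solve(X.T @ X, X.T @ y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_discount_model(rows, 1, MCMCConfig(seed=2, **REDUCED_MCMC))
    names = ["Intercept", "Time", "Time^2"]
    flat = fit.flat(fit.beta)
    for k, name in enumerate(names):
        post_sd = flat[:, k].std(ddof=1)
        assert abs(fit.summary.loc[name, "estimate"] - ols[k]) < 2 * post_sd


def test_fit_validates_input(small_cohort):
    with pytest.raises(ValueError, match="valence"):
        fit_discount_model(small_cohort.panel, 0)
    single = small_cohort.panel[
        small_cohort.panel["participant_id"] == "p0001"]
    with pytest.raises(ValueError, match="2 participants"):
        fit_discount_model(single, 1)


def test_mcmc_config_validation():
    with pytest.raises(ValueError, match="n_warmup"):
        MCMCConfig(n_iterations=100, n_warmup=100)
    with pytest.raises(ValueError, match="chains"):
        MCMCConfig(n_chains=1)
    with pytest.raises(ValueError, match="degree"):
        MCMCConfig(degree=4)


def test_prior_insensitivity(small_cohort):
    """Doubling every prior scale moves the fixed-effect posterior means by
    less than 5%: the data dominate at this cohort size."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base = fit_discount_model(small_cohort.panel, 1,
                                  MCMCConfig(seed=5, **REDUCED_MCMC))
        wide = fit_discount_model(small_cohort.panel, 1,
                                  MCMCConfig(seed=5, prior_scale=2.0,
                                             **REDUCED_MCMC))
    for name in ("Intercept", "Time", "Time^2"):
        a = base.summary.loc[name, "estimate"]
        b = wide.summary.loc[name, "estimate"]
        assert abs(b - a) / abs(a) < 0.05


def test_fixed_effect_coverage_over_simulated_cohorts():
    """Parameter recovery across replicated small cohorts: each generating
    fixed effect falls inside its 95% HPDI in >= 85% of 20 runs."""
    truth = np.array([67.806, -0.816, 0.007])
    inside = np.zeros(3)
    n_runs = 20
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for r in range(n_runs):
            data = simulate_cohort(CohortConfig(n_participants=40,
                                                seed=1000 + r))
            fit = fit_discount_model(
                data.panel, 1,
                MCMCConfig(n_chains=2, n_iterations=15000, n_warmup=1000,
                           thin=10, seed=2000 + r))
            for k, name in enumerate(["Intercept", "Time", "Time^2"]):
                row = fit.summary.loc[name]
                inside[k] += row["hpdi_low"] <= truth[k] <= row["hpdi_high"]
    assert (inside >= 0.85 * n_runs).all(), inside


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def test_rhat_near_one_for_iid_chains():
    rng = np.random.default_rng(3)
    table = rhat_ess({"x": rng.standard_normal((4, 2000))})
    assert table.loc["x", "rhat"] < 1.01
    assert table.loc["x", "rhat_ok"]
    assert table.loc["x", "ess_bulk"] > 1000


def test_rhat_flags_disjoint_chains():
    rng = np.random.default_rng(4)
    chains = np.stack([rng.standard_normal(1000),
                       rng.standard_normal(1000) + 10.0])
    table = rhat_ess({"x": chains})
    assert table.loc["x", "rhat"] > 1.5
    assert not table.loc["x", "rhat_ok"]


def test_rhat_requires_two_chains():
    with pytest.raises(ValueError, match="2 chains"):
        rhat_ess({"x": np.zeros((1, 100))})


def test_default_fit_meets_convergence_conventions(reference_fits):
    """At default sampler settings on the reference design, every parameter
    clears R-hat < 1.01 and the reported trajectory parameters (intercept,
    linear, quadratic) have bulk-ESS > 1000."""
    for fit in reference_fits.values():
        table = convergence_diagnostics(fit)
        assert (table["rhat"] < 1.01).all(), table
        for name in ("Intercept", "Time", "Time^2"):
            assert table.loc[name, "ess_bulk"] > 1000


def test_convergence_error_raised_for_bad_rhat():
    import pandas as pd

    from ptdkit.model import ConvergenceError, _check_convergence
    summary = pd.DataFrame({"rhat": [1.2], "ess_bulk": [50.0]},
                           index=["Intercept"])
    with pytest.raises(ConvergenceError, match="Intercept"):
        _check_convergence(summary, MCMCConfig())


# ---------------------------------------------------------------------------
# Posterior predictive checks
# ---------------------------------------------------------------------------

def test_ppc_self_consistent_for_model_generated_data(small_fits,
                                                      small_cohort):
    ppc = posterior_predictive_check(small_fits[1], small_cohort.panel,
                                     n_reps=60, seed=0)
    assert ppc.good_fit
    assert ppc.p_value > 0.05
    assert set(ppc.density_overlay.columns) == {
        "affect", "observed_density", "replicated_density"}


def test_ppc_detects_injected_cubic_misfit(small_fits, small_cohort):
    panel = small_cohort.panel.copy()
    t = panel["time_distance_days"].to_numpy(float)
    bump = 60.0 * ((t - 33.0) / 29.5) ** 3
    panel.loc[panel["valence"] == 1, "affect_rating"] = (
        panel.loc[panel["valence"] == 1, "affect_rating"]
        + bump[panel["valence"] == 1])
    ppc = posterior_predictive_check(small_fits[1], panel, n_reps=60, seed=0)
    assert not ppc.good_fit
    assert ppc.p_value < 0.05


# ---------------------------------------------------------------------------
# Derived curves
# ---------------------------------------------------------------------------

def test_marginal_curve_point_mass_equals_polynomial():
    coefs = np.tile([67.806, -0.816, 0.007], (5, 1))
    fit = make_point_mass_fit(coefs)
    grid = np.arange(4, 64)
    curve = marginal_effect_curve(fit, grid)
    expect = QuadraticPath(67.806, -0.816, 0.007)(grid)
    np.testing.assert_allclose(curve["mean"], expect)
    np.testing.assert_allclose(curve["hpdi_low"], expect)
    # intensity declines over the window at a decelerating rate (the curve
    # flattens out; the quadratic's vertex sits near day 58)
    assert curve["mean"].iloc[-1] < curve["mean"].iloc[0]
    first_diff = np.diff(curve["mean"])
    assert first_diff[0] < 0
    assert (np.diff(first_diff) > 0).all()


def test_marginal_curve_mean_is_polynomial_of_mean_coefs(small_fits):
    fit = small_fits[1]
    grid = np.arange(4, 64, dtype=float)
    curve = marginal_effect_curve(fit, grid)
    V = np.vander(grid, 3, increasing=True)
    np.testing.assert_allclose(curve["mean"], V @ fit.fixed_effect_means(),
                               rtol=1e-10)
    with pytest.warns(UserWarning, match="extrapolat"):
        marginal_effect_curve(fit, np.arange(1, 10))


def test_unobserved_participants_collapse_without_heterogeneity():
    coefs = np.tile([67.806, -0.816, 0.007], (5, 1))
    fit = make_point_mass_fit(coefs, Sigma=np.zeros((3, 3)))
    pred = predict_unobserved_participants(fit, n_new=20, seed=1)
    expect = QuadraticPath(67.806, -0.816, 0.007)(pred["t_grid"])
    np.testing.assert_allclose(pred["curves"],
                               np.tile(expect, (len(pred["curves"]), 1)))


def test_unobserved_participant_spread_grows_with_intercept_sd():
    coefs = np.tile([67.806, -0.816, 0.007], (5, 1))
    small = make_point_mass_fit(coefs, Sigma=np.diag([4.0, 0, 0]))
    large = make_point_mass_fit(coefs, Sigma=np.diag([100.0, 0, 0]))
    p_small = predict_unobserved_participants(small, n_new=300, seed=2)
    p_large = predict_unobserved_participants(large, n_new=300, seed=2)
    assert (p_large["summary"]["sd"].to_numpy()
            > p_small["summary"]["sd"].to_numpy()).all()
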