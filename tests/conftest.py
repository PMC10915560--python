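"""Shared fixtures: simulated cohorts and fitted models at two scales.

The small cohort (40 participants, reduced draws) backs most unit tests;
the full-size cohort (210 participants, default draws) backs the
parameter-recovery and diagnostics checks and is computed once per session.
"""

import warnings

import numpy as np
import pytest

from ptdkit import CohortConfig, MCMCConfig, fit_discount_model, simulate_cohort
from ptdkit.model import PosteriorFit

#: fast sampler settings for unit tests on small cohorts
REDUCED_MCMC = dict(n_iterations=3000, n_warmup=500, thin=2)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(CohortConfig(n_participants=40, seed=11))


@pytest.fixture(scope="session")
def small_fits(small_cohort):
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for valence in (1, -1):
            fits[valence] = fit_discount_model(
                small_cohort.panel, valence,
                MCMCConfig(seed=100 + valence, **REDUCED_MCMC))
    return fits


@pytest.fixture(scope="session")
def full_cohort():
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def reference_fits(full_cohort):
    """Both valences fitted at default sampler settings (minutes)."""
    fits = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for valence, seed in ((1, 3), (-1, 4)):
            fits[valence] = fit_discount_model(
                full_cohort.panel, valence, MCMCConfig(seed=seed))
    return fits


def make_point_mass_fit(coefs, valence=1, Sigma=None, sigma=5.0,
                        sd_event=0.0):
    """A PosteriorFit whose posterior is concentrated at given participant
    coefficient vectors (P, d): every draw identical.  Useful for exercising
    scoring and curve utilities without running the sampler."""
    coefs = np.asarray(coefs, dtype=float)
    P, d = coefs.shape
    beta = coefs.mean(axis=0)
    u = coefs - beta[None, :]
    C, D = 2, 4
    Sigma = np.zeros((d, d)) if Sigma is None else np.asarray(Sigma, float)
    pids = np.array([f"p{i:04d}" for i in range(1, P + 1)])
    eids = np.array([f"{p}_ev1" for p in pids])
    return PosteriorFit(
        valence=valence,
        participant_ids=pids,
        event_ids=eids,
        event_participant_index=np.arange(P),
        degree=d - 1,
        beta=np.broadcast_to(beta, (C, D, d)).copy(),
        Sigma_u=np.broadcast_to(Sigma, (C, D, d, d)).copy(),
        sd_event=np.full((C, D), sd_event),
        sigma=np.full((C, D), sigma),
        u=np.broadcast_to(u, (C, D, P, d)).copy(),
        e=np.zeros((C, D, P)),
        config=MCMCConfig(n_iterations=8, n_warmup=4, thin=1),
    )
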