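"""Synthetic longitudinal affect-recall cohorts.

Emulates the study design the analysis assumes: each participant recalls 3
positive and 3 negative autobiographical events from the past month (events
dated 0..31 days before baseline, encoding intensity at least 35 on a 0-100
scale), then rates the affect elicited by recalling each event on a -100..100
visual-analog scale at 8 follow-up waves spaced 4 days apart.  Time distance
(event day to rating day) therefore spans 4..63 days.

The generative model mirrors the hierarchical quadratic model fitted
downstream: affect = (b0 + u0_i + e0_ij) + (b1 + u1_i) t + (b2 + u2_i) t^2
+ noise, with participant-level deviations u_i drawn jointly per valence,
the two valences' intercept deviations coupled by a configurable
correlation, event intercept deviations nested within participants, and
ratings clipped to the VAS bounds (clipping is counted and logged).

Mental-health scale totals (WEMWBS, BDI, TAI, PSS, RRS) are generated from a
linear latent model on the participant's *true* standardized AUC scores, so
downstream regressions have a known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import DEFAULT_T_GRID, QuadraticPath, auc_exact_quadratic

logger = logging.getLogger("ptdkit.cohort")

__all__ = [
    "CohortConfig",
    "TruthRecord",
    "CohortData",
    "SCALE_RANGES",
    "DEFAULT_SCALE_EFFECTS",
    "build_event_schedule",
    "sample_true_paths",
    "generate_affect_panel",
    "generate_scale_scores",
    "simulate_cohort",
]

#: Instrument ranges for the five analyzed questionnaire totals.
SCALE_RANGES: dict[str, tuple[int, int]] = {
    "wemwbs": (14, 70),   # Warwick-Edinburgh Mental Well-Being Scale
    "bdi": (0, 63),       # Beck Depression Inventory
    "tai": (20, 80),      # Trait Anxiety Inventory
    "pss": (0, 40),       # Perceived Stress Scale
    "rrs": (22, 88),      # Ruminative Responses Scale
}

#: Default standardized effects (gamma_pos, gamma_neg) of the true AUC scores
#: on each scale's latent score: well-being rises with slow positive-event
#: discounting and falls with slow negative-event discounting; the four
#: distress scales show the mirrored pattern.
DEFAULT_SCALE_EFFECTS: dict[str, tuple[float, float]] = {
    "wemwbs": (0.284, -0.133),
    "bdi": (-0.131, 0.139),
    "tai": (-0.178, 0.164),
    "pss": (-0.162, 0.149),
    "rrs": (-0.12, 0.147),
}


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


def _default_corr() -> np.ndarray:
    return np.eye(3)


@dataclass
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    Fixed effects default to the population-level quadratic trajectories of
    recalled affect (intercept in affect units at t=0, linear in units/day,
    quadratic in units/day^2) for positive and negative events.  Variance
    components (participant-level deviation SDs, event-intercept SD, residual
    SD) are design choices, not estimates: they are set so that simulated
    spaghetti plots show a realistic spread of trajectories.
    """

    n_participants: int = 210
    n_events_per_valence: int = 3
    n_waves: int = 8
    wave_interval_days: int = 4
    max_event_age_at_baseline_days: int = 31
    fixed_effects_pos: QuadraticPath = field(
        default_factory=lambda: QuadraticPath(67.806, -0.816, 0.007))
    fixed_effects_neg: QuadraticPath = field(
        default_factory=lambda: QuadraticPath(-51.569, 0.683, -0.006))
    re_sd_participant: tuple[float, float, float] = (10.0, 0.15, 0.002)
    re_corr_participant: np.ndarray = field(default_factory=_default_corr)
    cross_valence_corr: float = 0.4
    re_sd_event_intercept: float = 8.0
    residual_sd: float = 12.0
    #: per-scale (gamma_pos, gamma_neg); latent noise SD is
    #: sqrt(1 - gamma_pos^2 - gamma_neg^2) so latent scores are ~unit variance.
    scale_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCALE_EFFECTS))
    encoding_intensity_mean: float = 65.0
    encoding_intensity_sd: float = 15.0
    seed: int = 0

    def __post_init__(self):
        self.re_corr_participant = np.asarray(self.re_corr_participant, float)
        self.validate()

    @property
    def max_time_distance(self) -> int:
        return (self.n_waves * self.wave_interval_days
                + self.max_event_age_at_baseline_days)

    def validate(self) -> None:
        for name in ("n_participants", "n_events_per_valence", "n_waves",
                     "wave_interval_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.max_event_age_at_baseline_days < 0:
            raise ConfigurationError(
                "max_event_age_at_baseline_days must be non-negative")
        sds = np.asarray(self.re_sd_participant, float)
        if np.any(sds < 0) or self.re_sd_event_intercept < 0 \
                or self.residual_sd < 0:
            raise ConfigurationError("all SDs must be non-negative")
        R = self.re_corr_participant
        if R.shape != (3, 3) or not np.allclose(R, R.T):
            raise ConfigurationError(
                "re_corr_participant must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ConfigurationError(
                "re_corr_participant must have unit diagonal")
        if np.min(np.linalg.eigvalsh(R)) < -1e-10:
            raise ConfigurationError(
                "re_corr_participant is not positive semi-definite")
        if not -1.0 <= self.cross_valence_corr <= 1.0:
            raise ConfigurationError("cross_valence_corr must lie in [-1, 1]")
        if np.min(np.linalg.eigvalsh(self._joint_correlation())) < -1e-10:
            raise ConfigurationError(
                "joint cross-valence correlation matrix is not positive "
                "semi-definite")
        for scale, (g_pos, g_neg) in self.scale_effects.items():
            if scale not in SCALE_RANGES:
                raise ConfigurationError(f"unknown scale {scale!r}")
            if g_pos**2 + g_neg**2 > 1.0:
                raise ConfigurationError(
                    f"scale {scale!r}: effects imply latent R^2 > 1")
        if not 35 <= self.encoding_intensity_mean <= 100:
            raise ConfigurationError(
                "encoding_intensity_mean must lie in [35, 100]")

    def _joint_correlation(self) -> np.ndarray:
        """6x6 correlation of the stacked (positive, negative) participant
        deviations; only the two intercept deviations are cross-correlated.

        ``cross_valence_corr`` couples affect *intensity*: a positive value
        means participants with more intense positive-event affect also feel
        negative events more intensely (a more negative intercept), which is
        what makes the two discounting rates positively correlated
        downstream.  On the raw intercept scale that is a correlation of
        -cross_valence_corr, because negative-event intercepts point down.
        """
        R = np.zeros((6, 6))
        R[:3, :3] = self.re_corr_participant
        R[3:, 3:] = self.re_corr_participant
        R[0, 3] = R[3, 0] = -self.cross_valence_corr
        return R

    def joint_participant_covariance(self) -> np.ndarray:
        sds = np.concatenate([self.re_sd_participant, self.re_sd_participant])
        return self._joint_correlation() * np.outer(sds, sds)

    def participant_covariance(self) -> np.ndarray:
        sds = np.asarray(self.re_sd_participant, float)
        return self.re_corr_participant * np.outer(sds, sds)


@dataclass
class TruthRecord:
    """Ground truth behind a simulated cohort, for recovery tests."""

    participant_ids: np.ndarray
    paths_pos: np.ndarray          # (P, 3) true participant coefficients
    paths_neg: np.ndarray          # (P, 3)
    event_intercepts: pd.DataFrame  # event_id, participant_id, valence, deviation
    true_auc_pos: np.ndarray       # (P,) exact scaled-curve integrals
    true_auc_neg: np.ndarray
    scale_effects: dict[str, tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "participant_ids": self.participant_ids.tolist(),
            "paths_pos": self.paths_pos.tolist(),
            "paths_neg": self.paths_neg.tolist(),
            "event_intercepts": self.event_intercepts.to_dict(orient="list"),
            "true_auc_pos": self.true_auc_pos.tolist(),
            "true_auc_neg": self.true_auc_neg.tolist(),
            "scale_effects": {k: list(v) for k, v in self.scale_effects.items()},
        }


@dataclass
class CohortData:
    """Everything one simulated cohort produces."""

    encoding: pd.DataFrame
    schedule: pd.DataFrame
    panel: pd.DataFrame
    scales: pd.DataFrame
    truth: TruthRecord
    n_clipped: int
    clip_fraction: float
    config: CohortConfig


# ---------------------------------------------------------------------------
# Generation steps
# ---------------------------------------------------------------------------

def _participant_ids(n: int) -> np.ndarray:
    return np.array([f"p{i:04d}" for i in range(1, n + 1)])


def build_event_schedule(config: CohortConfig, seed: int | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw event dates and encoding intensities; lay out the follow-up grid.

    Events happen uniformly within the month before baseline (day offsets
    -max_age..0); wave w falls on day w * wave_interval after baseline, so
    the time distance for (event, wave) is w * interval - event_day, strictly
    increasing across waves.  Encoding intensity is truncated-normal on
    [35, 100] (ratings below 35 would not reliably arouse affect on recall
    and are re-reported in the real protocol).

    Returns ``(encoding, schedule)`` tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pids = _participant_ids(config.n_participants)
    K = config.n_events_per_valence
    n_events = config.n_participants * 2 * K
    lo, hi = 35.0, 100.0
    mu, sd = config.encoding_intensity_mean, config.encoding_intensity_sd
    a, b = (lo - mu) / sd, (hi - mu) / sd

    pid_col = np.repeat(pids, 2 * K)
    valence = np.tile(np.repeat([1, -1], K), config.n_participants)
    tag = np.where(valence == 1, "pos", "neg")
    within = np.tile(np.arange(1, K + 1), 2 * config.n_participants)
    event_id = np.array([f"{p}_{t}{k}" for p, t, k in
                         zip(pid_col, tag, within)])
    event_day = -rng.integers(0, config.max_event_age_at_baseline_days + 1,
                              size=n_events)
    intensity = np.round(stats.truncnorm.rvs(
        a, b, loc=mu, scale=sd, size=n_events, random_state=rng))
    encoding = pd.DataFrame({
        "participant_id": pid_col, "event_id": event_id, "valence": valence,
        "event_day": event_day, "encoding_intensity": intensity})

    waves = np.arange(1, config.n_waves + 1)
    schedule = encoding.loc[encoding.index.repeat(config.n_waves),
                            ["participant_id", "event_id", "valence",
                             "event_day"]].reset_index(drop=True)
    schedule["wave"] = np.tile(waves, len(encoding))
    schedule["time_distance_days"] = (
        schedule["wave"] * config.wave_interval_days - schedule["event_day"])
    schedule = schedule.drop(columns="event_day")
    return encoding, schedule


def sample_true_paths(config: CohortConfig, seed: int | None = None,
                      encoding: pd.DataFrame | None = None) -> TruthRecord:
    """Draw the latent hierarchical structure of a cohort.

    Participant deviations (intercept, linear, quadratic) are drawn jointly
    for both valences from a 6x6 Gaussian whose only cross-valence coupling
    is the intercept correlation; event intercept deviations are nested
    within participants.  True per-participant AUCs are the closed-form
    scaled-curve integrals of the true paths.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    P = config.n_participants
    pids = _participant_ids(P)

    cov = config.joint_participant_covariance()
    # eigendecomposition root: tolerates singular covariances (zero SDs)
    w, V = np.linalg.eigh(cov)
    root = V * np.sqrt(np.clip(w, 0.0, None))
    dev = rng.standard_normal((P, 6)) @ root.T
    beta_pos = config.fixed_effects_pos.as_array()
    beta_neg = config.fixed_effects_neg.as_array()
    paths_pos = beta_pos[None, :] + dev[:, :3]
    paths_neg = beta_neg[None, :] + dev[:, 3:]

    if encoding is None:
        encoding, _ = build_event_schedule(config, seed=config.seed)
    ev = encoding[["event_id", "participant_id", "valence"]].copy()
    ev["deviation"] = rng.standard_normal(len(ev)) * config.re_sd_event_intercept

    true_auc_pos = np.array([
        auc_exact_quadratic(QuadraticPath(*row)) for row in paths_pos])
    true_auc_neg = np.array([
        auc_exact_quadratic(QuadraticPath(*row)) for row in paths_neg])
    return TruthRecord(pids, paths_pos, paths_neg, ev,
                       true_auc_pos, true_auc_neg,
                       dict(config.scale_effects))


def generate_affect_panel(truth: TruthRecord, schedule: pd.DataFrame,
                          config: CohortConfig, seed: int | None = None
                          ) -> tuple[pd.DataFrame, int]:
    """Evaluate event-level paths on the follow-up grid and add noise.

    rating = participant path + event intercept deviation + Gaussian residual,
    clipped to the VAS bounds [-100, 100].  Returns the panel and the number
    of clipped ratings (also logged as a fraction).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pid_index = {p: i for i, p in enumerate(truth.participant_ids)}
    idx = schedule["participant_id"].map(pid_index).to_numpy()
    if np.any(pd.isna(idx)):
        raise ValueError("schedule references participants missing from truth")
    pos = schedule["valence"].to_numpy() == 1
    coefs = np.where(pos[:, None], truth.paths_pos[idx], truth.paths_neg[idx])

    ev_dev = truth.event_intercepts.set_index("event_id")["deviation"]
    e = schedule["event_id"].map(ev_dev).to_numpy()

    t = schedule["time_distance_days"].to_numpy(dtype=float)
    mean = coefs[:, 0] + e + coefs[:, 1] * t + coefs[:, 2] * t * t
    noise = rng.standard_normal(len(schedule)) * config.residual_sd
    raw = mean + noise
    rating = np.clip(raw, -100.0, 100.0)
    n_clipped = int(np.sum(raw != rating))
    frac = n_clipped / len(raw)
    logger.info("affect panel: %d ratings, %d clipped to VAS bounds (%.3f%%)",
                len(raw), n_clipped, 100 * frac)

    panel = schedule[["participant_id", "event_id", "valence", "wave",
                      "time_distance_days"]].copy()
    panel["affect_rating"] = np.round(rating, 3)
    return panel, n_clipped


def generate_scale_scores(truth: TruthRecord, config: CohortConfig,
                          seed: int | None = None) -> pd.DataFrame:
    """Questionnaire totals linked to the true discounting rates.

    latent = gamma_pos * z(true AUC-pos) + gamma_neg * z(true AUC-neg) +
    noise, with noise SD chosen so latent variance is ~1; the latent score is
    mapped affinely into the instrument range (centre = range midpoint, SD =
    one sixth of the range), rounded to integer totals, and clipped.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    def _z(x):
        if len(x) < 2:
            return np.zeros_like(x)
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    z_pos = _z(truth.true_auc_pos)
    z_neg = _z(truth.true_auc_neg)
    out = {"participant_id": truth.participant_ids}
    for scale, (g_pos, g_neg) in config.scale_effects.items():
        noise_var = 1.0 - g_pos**2 - g_neg**2
        if noise_var < 0:
            raise ConfigurationError(
                f"scale {scale!r}: effects imply latent R^2 > 1")
        latent = (g_pos * z_pos + g_neg * z_neg
                  + rng.standard_normal(len(z_pos)) * np.sqrt(noise_var))
        lo, hi = SCALE_RANGES[scale]
        centre, spread = (lo + hi) / 2.0, (hi - lo) / 6.0
        score = np.clip(np.round(centre + spread * latent), lo, hi)
        out[scale] = score.astype(int)
    return pd.DataFrame(out)


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Run the full generator: schedule, latent truth, panel, scale scores.

    Deterministic given ``config.seed``; each stage uses an independent
    child stream so changing one stage's structure does not reshuffle the
    others.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_sched, s_truth, s_panel, s_scales = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    encoding, schedule = build_event_schedule(config, seed=s_sched)
    truth = sample_true_paths(config, seed=s_truth, encoding=encoding)
    panel, n_clipped = generate_affect_panel(truth, schedule, config,
                                             seed=s_panel)
    scales = generate_scale_scores(truth, config, seed=s_scales)
    return CohortData(encoding=encoding, schedule=schedule, panel=panel,
                      scales=scales, truth=truth, n_clipped=n_clipped,
                      clip_fraction=n_clipped / len(panel), config=config)
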