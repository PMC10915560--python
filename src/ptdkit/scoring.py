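"""Discounting-rate scores from fitted affect trajectories.

A participant's past-temporal-discounting (PTD) rate is summarized by the
area under their *scaled* affect-recall curve: predicted affect intensity is
evaluated on integer time distances 4..63 days, the time axis is mapped onto
[0, 1] (subtract 4, divide by 59) and the affect axis is divided by its first
predicted value, so every curve starts at (0, 1).  An AUC of 1 means no
discounting; smaller values mean faster discounting; negative values indicate
a sign-flipped curve and are grounds for exclusion.

Dividing by the first predicted value makes the scaled curve positive for
negative-valence paths too (no absolute values are taken anywhere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QuadraticPath",
    "DiscountCurve",
    "AUCRecord",
    "AbnormalPatternScreen",
    "ScalingError",
    "DEFAULT_T_GRID",
    "predict_affect_grid",
    "scale_discount_curve",
    "auc_trapezoid",
    "auc_exact_quadratic",
    "extract_individual_paths",
    "score_cohort",
    "ptd_bias",
]

#: Integer time distances (days) the study design spans: first follow-up at
#: 4 days, last at 32 days for an event on the baseline day, up to 63 days
#: for an event 31 days before baseline.
DEFAULT_T_GRID = np.arange(4, 64)

T_MIN = 4
T_SPAN = 59  # 63 - 4


class ScalingError(ValueError):
    """Raised when a curve cannot be scaled (first predicted value is zero)."""


@dataclass(frozen=True)
class QuadraticPath:
    """Coefficients of an affect-vs-time-distance polynomial.

    ``b0`` is the affect intensity at time distance 0 (affect units), ``b1``
    the linear rate (units/day) and ``b2`` the curvature (units/day^2).
    Time is in raw days, never centred or rescaled.
    """

    b0: float
    b1: float
    b2: float

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.b0 + self.b1 * t + self.b2 * t * t

    def as_array(self) -> np.ndarray:
        return np.array([self.b0, self.b1, self.b2], dtype=float)


@dataclass
class DiscountCurve:
    """A scaled PTD curve: time mapped to [0, 1], affect divided by its
    first predicted value so the curve starts at exactly 1."""

    scaled_time: np.ndarray
    scaled_affect: np.ndarray
    participant_id: object | None = None
    valence: int | None = None


@dataclass
class AUCRecord:
    """One participant's discounting-rate scores.

    Tabular results use a DataFrame with these columns; this container is
    the row-level view for callers that prefer objects.
    """

    participant_id: object
    auc_pos: float
    auc_neg: float
    included: bool
    exclusion_reason: str
    ptd_bias: float

    @classmethod
    def from_frame(cls, records: pd.DataFrame) -> list["AUCRecord"]:
        return [cls(**row) for row in records.to_dict(orient="records")]


@dataclass
class AbnormalPatternScreen:
    """Configurable stand-in screen for grossly atypical response patterns.

    Flags participants whose mean rating sign contradicts the event valence
    in at least ``min_fraction`` of follow-up waves.  Off by default: the
    synthetic generator does not produce such participants except through
    extreme noise.
    """

    enabled: bool = False
    min_fraction: float = 0.5


def predict_affect_grid(path: QuadraticPath, t_grid=DEFAULT_T_GRID) -> np.ndarray:
    """Evaluate a path on a grid of time distances (days)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("empty time grid")
    if t_grid.min() < T_MIN or t_grid.max() > T_MIN + T_SPAN:
        raise ValueError(
            f"time grid must lie within [{T_MIN}, {T_MIN + T_SPAN}] days"
        )
    return path(t_grid)


def scale_discount_curve(values, t_grid=DEFAULT_T_GRID, *, participant_id=None,
                         valence=None) -> DiscountCurve:
    """Scale a predicted-affect curve onto the unit square.

    x = (t - 4) / 59 and y = v / v[first]; by construction y[0] == 1.
    Raises :class:`ScalingError` if the first predicted value is zero.
    """
    values = np.asarray(values, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if values.shape != t_grid.shape:
        raise ValueError("values and t_grid must have matching shapes")
    if values[0] == 0.0:
        raise ScalingError(
            f"first predicted value is zero for participant {participant_id!r}; "
            "curve cannot be scaled"
        )
    x = (t_grid - T_MIN) / T_SPAN
    y = values / values[0]
    y[0] = 1.0
    return DiscountCurve(x, y, participant_id=participant_id, valence=valence)


def auc_trapezoid(curve: DiscountCurve) -> float:
    """Composite trapezoid AUC of a scaled curve over its grid.

    May be negative when the curve crosses zero and the flipped tail
    dominates; such values violate the definition of a discounting rate and
    are flagged downstream.
    """
    if curve.scaled_time.size < 2:
        raise ValueError("AUC needs at least two grid points")
    return float(np.trapezoid(curve.scaled_affect, curve.scaled_time))


def auc_exact_quadratic(path: QuadraticPath, t_min: float = T_MIN,
                        t_max: float = T_MIN + T_SPAN) -> float:
    """Closed-form AUC of the scaled curve of a quadratic path.

    AUC = (1 / ((t_max - t_min) * v(t_min))) * integral_{t_min}^{t_max} v(t) dt,
    the exact value the trapezoid rule approaches as the grid refines.
    """
    v0 = float(path(t_min))
    if v0 == 0.0:
        raise ScalingError("path evaluates to zero at the first time distance")
    integral = (
        path.b0 * (t_max - t_min)
        + path.b1 / 2.0 * (t_max**2 - t_min**2)
        + path.b2 / 3.0 * (t_max**3 - t_min**3)
    )
    return integral / ((t_max - t_min) * v0)


# ---------------------------------------------------------------------------
# Individual paths from a fitted model
# ---------------------------------------------------------------------------

def extract_individual_paths(fit, participant_ids=None) -> pd.DataFrame:
    """Per-participant paths: posterior-mean fixed effects plus the posterior
    mean of that participant's deviations.

    Event-level deviations are averaged out (excluded): the individual path
    characterizes the participant, not any single event.  Returns a frame
    indexed by participant with columns ``b0, b1, b2`` (and ``b3`` for a
    cubic fit).
    """
    beta = fit.fixed_effect_means()
    dev = fit.participant_deviation_means()
    ids = list(fit.participant_ids)
    coefs = beta[None, :] + dev
    cols = ["b0", "b1", "b2", "b3"][: coefs.shape[1]]
    frame = pd.DataFrame(coefs, index=pd.Index(ids, name="participant_id"),
                         columns=cols)
    if participant_ids is not None:
        missing = [p for p in participant_ids if p not in frame.index]
        if missing:
            raise KeyError(f"participants absent from fit: {missing}")
        frame = frame.loc[list(participant_ids)]
    return frame


def _auc_for_coefs(coefs: np.ndarray, t_grid: np.ndarray) -> float:
    """AUC of one coefficient vector (length 3) via scale + trapezoid."""
    path = QuadraticPath(*coefs[:3])
    values = predict_affect_grid(path, t_grid)
    try:
        curve = scale_discount_curve(values, t_grid)
    except ScalingError:
        return np.nan
    return auc_trapezoid(curve)


def _abnormal_flags(panel: pd.DataFrame, screen: AbnormalPatternScreen) -> pd.Series:
    """Participants whose wave-mean rating sign contradicts event valence in
    >= ``min_fraction`` of waves, in either valence."""
    wave_means = (
        panel.groupby(["participant_id", "valence", "wave"])["affect_rating"]
        .mean()
        .reset_index()
    )
    wave_means["contradicts"] = (
        np.sign(wave_means["affect_rating"]) == -wave_means["valence"]
    )
    frac = wave_means.groupby(["participant_id", "valence"])["contradicts"].mean()
    flagged = frac[frac >= screen.min_fraction].reset_index()["participant_id"]
    all_ids = panel["participant_id"].unique()
    return pd.Series(np.isin(all_ids, flagged.unique()), index=all_ids)


def score_cohort(fit_pos, fit_neg, *, t_grid=DEFAULT_T_GRID,
                 screen: AbnormalPatternScreen | None = None,
                 panel: pd.DataFrame | None = None,
                 method: str = "posterior_mean",
                 bias_normalization: str = "zscore") -> pd.DataFrame:
    """Score every participant: AUC-positive, AUC-negative, exclusions, bias.

    ``method='posterior_mean'`` (default) extracts posterior-mean individual
    paths and computes one AUC each; ``method='per_draw'`` computes an AUC
    per posterior draw of the participant's coefficients and averages.
    Participants with any negative AUC are excluded (a negative area violates
    the definition of a discounting rate); the optional abnormal-pattern
    screen additionally flags implausible raters.  PTD bias is filled in for
    included participants.
    """
    ids_pos = list(fit_pos.participant_ids)
    ids_neg = list(fit_neg.participant_ids)
    if set(ids_pos) != set(ids_neg):
        raise ValueError(
            "positive- and negative-valence fits cover different participants"
        )
    t_grid = np.asarray(t_grid, dtype=float)

    def _aucs(fit) -> pd.Series:
        if method == "posterior_mean":
            frame = extract_individual_paths(fit)
            vals = {pid: _auc_for_coefs(row.to_numpy(), t_grid)
                    for pid, row in frame.iterrows()}
        elif method == "per_draw":
            draws = fit.participant_coefficient_draws()  # (n_draws, P, d)
            vals = {}
            for j, pid in enumerate(fit.participant_ids):
                per_draw = [_auc_for_coefs(draws[k, j], t_grid)
                            for k in range(draws.shape[0])]
                vals[pid] = float(np.nanmean(per_draw))
        else:
            raise ValueError(f"unknown scoring method {method!r}")
        return pd.Series(vals)

    auc_pos = _aucs(fit_pos)
    auc_neg = _aucs(fit_neg).reindex(auc_pos.index)

    records = pd.DataFrame({
        "participant_id": auc_pos.index,
        "auc_pos": auc_pos.to_numpy(),
        "auc_neg": auc_neg.to_numpy(),
    })
    records["included"] = True
    records["exclusion_reason"] = "none"

    negative = (records["auc_pos"] < 0) | (records["auc_neg"] < 0) | \
        records["auc_pos"].isna() | records["auc_neg"].isna()
    records.loc[negative, "included"] = False
    records.loc[negative, "exclusion_reason"] = "negative_auc"

    if screen is not None and screen.enabled:
        if panel is None:
            raise ValueError("abnormal-pattern screen requires the affect panel")
        flags = _abnormal_flags(panel, screen)
        abnormal = records["participant_id"].map(flags).fillna(False).astype(bool)
        hit = abnormal & records["included"]
        records.loc[hit, "included"] = False
        records.loc[hit, "exclusion_reason"] = "abnormal_pattern"

    records["ptd_bias"] = np.nan
    included = records["included"]
    if included.sum() >= 2:
        try:
            bias = ptd_bias(records, normalization=bias_normalization)
        except ValueError:
            pass  # degenerate AUC distribution: bias stays undefined
        else:
            records.loc[included, "ptd_bias"] = bias.to_numpy()
    return records


def ptd_bias(records: pd.DataFrame, normalization: str = "zscore") -> pd.Series:
    """Per-participant PTD bias: normalized AUC-positive minus normalized
    AUC-negative, over included participants only.

    Positive bias means negative events discount faster than positive ones
    (the fading-affect-bias direction).
    """
    sub = records[records["included"]]
    if len(sub) < 2:
        raise ValueError("PTD bias needs at least 2 included participants")

    def _norm(x: pd.Series) -> pd.Series:
        x = x.astype(float)
        if normalization == "zscore":
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError("zero variance in AUC scores; bias undefined")
            return (x - x.mean()) / sd
        if normalization == "minmax":
            span = x.max() - x.min()
            if span == 0:
                raise ValueError("zero range in AUC scores; bias undefined")
            return (x - x.min()) / span
        raise ValueError(f"unknown normalization {normalization!r}")

    bias = _norm(sub["auc_pos"]) - _norm(sub["auc_neg"])
    bias.index = sub["participant_id"].to_numpy()
    return bias
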