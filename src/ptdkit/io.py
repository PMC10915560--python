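"""Validated tabular readers and writers for the pipeline's artifacts.

All tables are comma-separated text with headers; the truth sidecar is JSON;
posterior draws of the reported parameters go to a columnar parquet file.
Readers validate schema and ranges and report offending rows by line number
(header = line 1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SCALE_RANGES, TruthRecord

__all__ = [
    "PanelValidationError",
    "read_affect_panel",
    "write_affect_panel",
    "read_scale_scores",
    "write_scale_scores",
    "write_truth",
    "read_truth",
    "write_posterior",
]

PANEL_COLUMNS = ["participant_id", "event_id", "valence", "wave",
                 "time_distance_days", "affect_rating"]


class PanelValidationError(ValueError):
    """A panel file violates the affect-observation schema."""


def _lines(index) -> str:
    return ", ".join(str(i + 2) for i in index[:10]) + \
        (" ..." if len(index) > 10 else "")


def read_affect_panel(path) -> pd.DataFrame:
    """Read and validate a long-format affect panel.

    Checks: required columns present; valence in {-1, +1}; wave and time
    distance positive integers; ratings numeric within [-100, 100]; no
    duplicate (participant, event, wave) rows.  Errors name line numbers.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise PanelValidationError(
            f"{path.name}: missing required columns {missing}")

    for col in ("valence", "wave", "time_distance_days", "affect_rating"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna()]
        if len(bad):
            raise PanelValidationError(
                f"{path.name}: non-numeric {col} at lines {_lines(bad)}")
        table[col] = coerced

    bad = table.index[~table["valence"].isin([-1, 1])]
    if len(bad):
        raise PanelValidationError(
            f"{path.name}: valence must be -1 or +1 at lines {_lines(bad)}")
    bad = table.index[(table["affect_rating"] < -100)
                      | (table["affect_rating"] > 100)]
    if len(bad):
        raise PanelValidationError(
            f"{path.name}: affect_rating outside [-100, 100] at lines "
            f"{_lines(bad)}")
    bad = table.index[(table["wave"] < 1) | (table["time_distance_days"] < 1)]
    if len(bad):
        raise PanelValidationError(
            f"{path.name}: non-positive wave or time distance at lines "
            f"{_lines(bad)}")

    dup = table.duplicated(["participant_id", "event_id", "wave"], keep=False)
    if dup.any():
        raise PanelValidationError(
            f"{path.name}: duplicate (participant, event, wave) rows at "
            f"lines {_lines(table.index[dup])}")
    return table[PANEL_COLUMNS]


def write_affect_panel(panel: pd.DataFrame, path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def read_scale_scores(path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path)
    if "participant_id" not in table.columns:
        raise PanelValidationError(f"{path.name}: missing participant_id")
    for scale, (lo, hi) in SCALE_RANGES.items():
        if scale not in table.columns:
            continue
        coerced = pd.to_numeric(table[scale], errors="coerce")
        bad = table.index[coerced.isna() | (coerced < lo) | (coerced > hi)]
        if len(bad):
            raise PanelValidationError(
                f"{path.name}: {scale} outside [{lo}, {hi}] or non-numeric "
                f"at lines {_lines(bad)}")
        table[scale] = coerced.astype(int)
    return table


def write_scale_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)


def write_truth(truth: TruthRecord, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth(path) -> TruthRecord:
    with open(path) as fh:
        raw = json.load(fh)
    return TruthRecord(
        participant_ids=np.array(raw["participant_ids"]),
        paths_pos=np.array(raw["paths_pos"]),
        paths_neg=np.array(raw["paths_neg"]),
        event_intercepts=pd.DataFrame(raw["event_intercepts"]),
        true_auc_pos=np.array(raw["true_auc_pos"]),
        true_auc_neg=np.array(raw["true_auc_neg"]),
        scale_effects={k: tuple(v) for k, v in raw["scale_effects"].items()},
    )


def write_posterior(fit, prefix: Path) -> None:
    """Persist a fit: Table-1-style summary CSV + scalar draws parquet."""
    prefix = Path(prefix)
    label = "positive" if fit.valence == 1 else "negative"
    summary = fit.summary.reset_index()
    summary.insert(0, "outcome", f"affect_intensity_{label}")
    summary.to_csv(prefix.with_suffix(".summary.csv"), index=False)
    draws = fit.scalar_draws()
    C, D = next(iter(draws.values())).shape
    frame = pd.DataFrame({k: v.ravel() for k, v in draws.items()})
    frame.insert(0, "chain", np.repeat(np.arange(C), D))
    frame.insert(1, "draw", np.tile(np.arange(D), C))
    frame.to_parquet(prefix.with_suffix(".draws.parquet"))
    dev = pd.DataFrame(
        fit.participant_deviation_means(),
        columns=[f"u{k}" for k in range(fit.n_coef)])
    dev.insert(0, "participant_id", fit.participant_ids)
    dev.to_csv(prefix.with_suffix(".participant_deviations.csv"), index=False)
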