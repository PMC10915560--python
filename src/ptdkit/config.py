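"""Pipeline configuration: one YAML file with per-stage sections.

All randomness descends from a single master seed; each stage draws its own
child stream, so results are reproducible end to end and stages stay
decoupled.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .cohort import CohortConfig
from .model import MCMCConfig
from .scoring import AbnormalPatternScreen

__all__ = ["ScoringConfig", "InferenceConfig", "PipelineConfig",
           "load_config", "save_config"]


@dataclass
class ScoringConfig:
    t_min: int = 4
    t_max: int = 63
    method: str = "posterior_mean"      # or "per_draw"
    bias_normalization: str = "zscore"  # or "minmax"
    screen: AbnormalPatternScreen = field(default_factory=AbnormalPatternScreen)

    def t_grid(self) -> np.ndarray:
        return np.arange(self.t_min, self.t_max + 1)


@dataclass
class InferenceConfig:
    n_perm: int = 1000
    alpha: float = 0.05
    n_power_sims: int = 200
    run_power: bool = False


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    seed: int = 0
    output_dir: str = "ptd_results"
    #: optional path to a real (or previously written) affect panel; when
    #: set, the simulate stage is skipped and the panel is loaded instead
    panel_path: str | None = None
    scales_path: str | None = None

    def stage_seeds(self) -> dict[str, int]:
        names = ["cohort", "fit_pos", "fit_neg", "scoring", "inference",
                 "power", "ppc"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: int(c.generate_state(1)[0] % (2**31))
                for n, c in zip(names, children)}


def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    return obj


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    from .scoring import QuadraticPath

    cohort_raw = dict(raw.get("cohort", {}))
    for key in ("fixed_effects_pos", "fixed_effects_neg"):
        if key in cohort_raw and isinstance(cohort_raw[key], dict):
            cohort_raw[key] = QuadraticPath(**cohort_raw[key])
    if "re_corr_participant" in cohort_raw:
        cohort_raw["re_corr_participant"] = np.asarray(
            cohort_raw["re_corr_participant"], float)
    if "re_sd_participant" in cohort_raw:
        cohort_raw["re_sd_participant"] = tuple(
            cohort_raw["re_sd_participant"])
    if "scale_effects" in cohort_raw:
        cohort_raw["scale_effects"] = {
            k: tuple(v) for k, v in cohort_raw["scale_effects"].items()}
    scoring_raw = dict(raw.get("scoring", {}))
    if "screen" in scoring_raw and isinstance(scoring_raw["screen"], dict):
        scoring_raw["screen"] = AbnormalPatternScreen(**scoring_raw["screen"])
    return PipelineConfig(
        cohort=CohortConfig(**cohort_raw),
        mcmc=MCMCConfig(**dict(raw.get("mcmc", {}))),
        scoring=ScoringConfig(**scoring_raw),
        inference=InferenceConfig(**dict(raw.get("inference", {}))),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "ptd_results")),
        panel_path=raw.get("panel_path"),
        scales_path=raw.get("scales_path"),
    )
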