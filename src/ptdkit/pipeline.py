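"""End-to-end pipeline: simulate (or load) -> fit both valences -> score ->
infer -> write artifacts.

Artifacts written to the configured output directory: the affect panel,
scale scores and truth sidecar (when simulated), per-valence posterior
summaries and draws, the AUC table, the tidy inference results (CSV + JSON
summary), and a structured log with clip rates, exclusion counts and
convergence flags.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from . import io as ptdio
from .cohort import simulate_cohort
from .config import PipelineConfig, save_config
from .inference import paired_permutation_test, power_simulation, \
    run_mental_health_models, spearman_permutation
from .model import fit_discount_model, posterior_predictive_check
from .scoring import score_cohort

logger = logging.getLogger("ptdkit.pipeline")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    panel: pd.DataFrame
    scales: pd.DataFrame
    fit_pos: object
    fit_neg: object
    auc_records: pd.DataFrame
    paired_test: object
    rate_correlation: object
    mental_health: pd.DataFrame
    power: dict | None
    output_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole analysis; see module docstring for the artifact list.

    Stage errors propagate annotated with the stage name; a convergence
    failure in either fit aborts the run.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ptdkit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seeds = config.stage_seeds()
    save_config(config, out / "config.yaml")

    try:
        if config.panel_path:
            stage = "load"
            panel = ptdio.read_affect_panel(config.panel_path)
            scales = ptdio.read_scale_scores(config.scales_path) \
                if config.scales_path else None
            truth = None
        else:
            stage = "simulate"
            cohort_cfg = replace(config.cohort, seed=seeds["cohort"])
            data = simulate_cohort(cohort_cfg)
            panel, scales, truth = data.panel, data.scales, data.truth
            logger.info("simulated cohort: %d participants, %d ratings, "
                        "clip fraction %.4f", cohort_cfg.n_participants,
                        len(panel), data.clip_fraction)
            ptdio.write_affect_panel(panel, out / "affect_panel.csv")
            ptdio.write_scale_scores(scales, out / "scales.csv")
            data.encoding.to_csv(out / "encoding.csv", index=False)
            ptdio.write_truth(truth, out / "truth.json")

        stage = "fit"
        fit_pos = fit_discount_model(
            panel, 1, replace(config.mcmc, seed=seeds["fit_pos"]))
        fit_neg = fit_discount_model(
            panel, -1, replace(config.mcmc, seed=seeds["fit_neg"]))
        for fit, name in ((fit_pos, "positive"), (fit_neg, "negative")):
            ptdio.write_posterior(fit, out / f"fit_{name}")
            logger.info("fit %s: max R-hat %.4f, min bulk-ESS %.0f", name,
                        fit.summary["rhat"].max(),
                        fit.summary["ess_bulk"].min())
        table1 = pd.concat([
            fit_pos.summary.reset_index().assign(
                outcome="affect_intensity_positive"),
            fit_neg.summary.reset_index().assign(
                outcome="affect_intensity_negative"),
        ])[["outcome", "parameter", "estimate", "hpdi_low", "hpdi_high",
            "rhat", "ess_bulk"]]
        table1.to_csv(out / "posterior_summary.csv", index=False)

        stage = "ppc"
        for fit, name in ((fit_pos, "positive"), (fit_neg, "negative")):
            ppc = posterior_predictive_check(fit, panel, n_reps=50,
                                             seed=seeds["ppc"])
            ppc.density_overlay.to_csv(
                out / f"ppc_overlay_{name}.csv", index=False)
            logger.info("ppc %s: p=%.3f good_fit=%s", name, ppc.p_value,
                        ppc.good_fit)

        stage = "score"
        records = score_cohort(
            fit_pos, fit_neg, t_grid=config.scoring.t_grid(),
            screen=config.scoring.screen, panel=panel,
            method=config.scoring.method,
            bias_normalization=config.scoring.bias_normalization)
        n_excl = int((~records["included"]).sum())
        logger.info("scoring: %d participants, %d excluded (%s)",
                    len(records), n_excl,
                    records.loc[~records["included"],
                                "exclusion_reason"].value_counts().to_dict())
        records.to_csv(out / "auc_table.csv", index=False)

        stage = "inference"
        inc = records[records["included"]]
        paired = paired_permutation_test(
            inc["auc_pos"].to_numpy(), inc["auc_neg"].to_numpy(),
            n_perm=config.inference.n_perm, seed=seeds["inference"])
        rate_corr = spearman_permutation(
            inc["auc_pos"].to_numpy(), inc["auc_neg"].to_numpy(),
            n_perm=config.inference.n_perm, seed=seeds["inference"] + 1)
        mh = None
        if scales is not None:
            mh = run_mental_health_models(
                records, scales, n_perm=config.inference.n_perm,
                seed=seeds["inference"] + 2)
            mh.to_csv(out / "mental_health_results.csv", index=False)

        power = None
        if config.inference.run_power:
            stage = "power"
            power = power_simulation(
                config.cohort, config.cohort.n_participants,
                n_sims=config.inference.n_power_sims,
                alpha=config.inference.alpha, seed=seeds["power"])

        summary = {
            "n_participants": int(records.shape[0]),
            "n_excluded": n_excl,
            "auc_pos_mean": float(inc["auc_pos"].mean()),
            "auc_pos_sd": float(inc["auc_pos"].std(ddof=1)),
            "auc_neg_mean": float(inc["auc_neg"].mean()),
            "auc_neg_sd": float(inc["auc_neg"].std(ddof=1)),
            "paired_t": paired.statistic,
            "paired_permutation_p": paired.permutation_p,
            "cohens_d": paired.effect_size_d,
            "rate_spearman_rho": rate_corr.statistic,
            "rate_spearman_permutation_p": rate_corr.permutation_p,
        }
        if power:
            summary["power"] = {k: v.power for k, v in power.items()}
        with open(out / "results.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        logger.info("pipeline complete: %s", summary)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        root.removeHandler(handler)
        handler.close()

    return PipelineResult(panel=panel, scales=scales, fit_pos=fit_pos,
                          fit_neg=fit_neg, auc_records=records,
                          paired_test=paired, rate_correlation=rate_corr,
                          mental_health=mh, power=power, output_dir=out)
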