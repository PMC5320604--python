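"""End-to-end synthetic study driver.

Chains task simulation -> agent simulation -> model fitting -> behavioural
and neural analyses into one reproducible report directory.  A single global
seed fans out into fixed per-stage, per-agent substreams (derived from the
agent's global index), so enlarging the cohort never perturbs the streams of
earlier agents.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bh
from . import neural as nr
from .config import StudyConfig
from .fitting import compare_models, fit_all_models, fits_to_frame
from .io import write_trials
from .models import FREE_PARAMS, predict_series, simulate_agent
from .task import generate_experiment

__all__ = ["run_study"]

# Fixed stage codes for seed fan-out; appending stages must not renumber
# existing ones.
_STAGE_TASK = 0
_STAGE_PARAMS = 1
_STAGE_AGENT = 2
_STAGE_NEURAL = 3
_STAGE_COVARIATE = 4
_STAGE_FIT = 5

logger = logging.getLogger("adaptpe")


def _agent_seed(seed: int, stage: int, agent_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), stage, agent_index])


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"study stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate_cohort(config: StudyConfig, seed: int):
    records = []
    trial_frames = []
    idx = 0
    for group, spec in config.groups.items():
        for j in range(spec.n):
            agent_id = f"{group}-{j:02d}"
            design = generate_experiment(
                config.task, seed=_agent_seed(seed, _STAGE_TASK, idx),
                agent_id=agent_id,
            )
            params = spec.draw_model_params(
                np.random.default_rng(_agent_seed(seed, _STAGE_PARAMS, idx))
            )
            trials = simulate_agent(
                params, design,
                np.random.default_rng(_agent_seed(seed, _STAGE_AGENT, idx)),
                miss_probability=config.task.miss_probability,
            )
            gen = spec.draw_neural_params(
                np.random.default_rng(_agent_seed(seed, _STAGE_PARAMS, idx))
            )
            series = nr.simulate_roi_responses(
                trials, gen,
                np.random.default_rng(_agent_seed(seed, _STAGE_NEURAL, idx)),
            )
            cov_rng = np.random.default_rng(
                _agent_seed(seed, _STAGE_COVARIATE, idx)
            )
            dose = float(cov_rng.normal(*spec.dose_to_scan))
            records.append({
                "agent_id": agent_id, "group": group, "index": idx,
                "true_params": params, "neural_gen": gen, "series": series,
                "trials": trials, "dose_to_scan": dose,
            })
            trial_frames.append(trials)
            idx += 1
    return records, pd.concat(trial_frames, ignore_index=True)


@_stage("fit")
def _fit_cohort(config: StudyConfig, seed: int, records) -> pd.DataFrame:
    fits = []
    for rec in records:
        agent_fits = fit_all_models(
            rec["trials"], models=config.fit_models,
            n_restarts=config.n_restarts,
            seed=_agent_seed(seed, _STAGE_FIT, rec["index"]),
        )
        rec["fits"] = {f.model_id: f for f in agent_fits}
        fits.extend(agent_fits)
    return fits_to_frame(fits)


@_stage("behavior")
def _analyze_behavior(config: StudyConfig, records) -> tuple[pd.DataFrame, dict]:
    rows = []
    for rec in records:
        perf = bh.performance_error(rec["trials"], by_sd=True)
        row = {"agent_id": rec["agent_id"], "group": rec["group"],
               "dose_to_scan": rec["dose_to_scan"]}
        row.update({f"perf_error_{k}": v for k, v in perf.items()})
        row["perf_error"] = perf["overall"]
        best_model = "PH2" if "PH2" in rec["fits"] else config.fit_models[-1]
        fit = rec["fits"][best_model]
        for name in FREE_PARAMS[best_model]:
            row[name] = getattr(fit.params, name)
        row["sigma_hat"] = fit.params.sigma
        mu = predict_series(fit.params, rec["trials"],
                            mu_init="first_prediction")
        row["model_r2"] = bh.model_r2(rec["trials"], mu)
        rows.append(row)
    cohort = pd.DataFrame(rows)

    stats_report: dict = {}
    groups = cohort["group"]
    perf = cohort["perf_error"].to_numpy()
    stats_report["perf_error_raw"] = bh.group_tests(
        perf, groups, control=config.control_group, parametric=True,
        posthoc_alpha=config.posthoc_alpha,
    )
    cov = cohort["dose_to_scan"].to_numpy()
    stats_report["perf_error_residualized"] = bh.group_tests(
        bh.residualize(perf, cov), groups, control=config.control_group,
        parametric=True, posthoc_alpha=config.posthoc_alpha,
    )
    r2 = cohort["model_r2"].to_numpy()
    stats_report["model_r2_residualized"] = bh.group_tests(
        bh.residualize(r2, cov), groups, control=config.control_group,
        parametric=True, posthoc_alpha=config.posthoc_alpha,
    )

    if "nu" in cohort.columns:
        contingency = {}
        for g in config.groups:
            if g == config.control_group:
                continue
            table = bh.scaling_contingency(
                cohort["nu"], groups, (g, config.control_group),
                epsilon=config.scaler_epsilon,
            )
            entry = {"counts": table.tolist(),
                     "rows": [g, config.control_group],
                     "cols": ["non_scaler", "scaler"]}
            if (table.sum(axis=0) > 0).all():
                chi2, df, p = bh.pearson_chi2(table)
                entry.update({"chi2": chi2, "df": df, "p": p})
            else:
                entry["note"] = "degenerate column; chi-square not computed"
            contingency[g] = entry
        stats_report["scaler_contingency"] = contingency
        try:
            reg = bh.performance_regression(cohort)
            stats_report["performance_regression"] = {
                name: {"coef": float(r["coef"]), "t": float(r["t"]),
                       "p": float(r["p"])}
                for name, r in reg.iterrows()
            }
        except ValueError as exc:
            stats_report["performance_regression"] = {"error": str(exc)}
    return cohort, stats_report


@_stage("neural")
def _analyze_neural(config: StudyConfig, records) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    slope_frames = []
    rows = []
    for rec in records:
        slopes = nr.estimate_pe_slopes(rec["series"], rec["trials"])
        sf = slopes.reset_index()
        sf.insert(0, "agent_id", rec["agent_id"])
        slope_frames.append(sf)
        row = {"agent_id": rec["agent_id"], "group": rec["group"],
               "dose_to_scan": rec["dose_to_scan"]}
        for signs, col in (("both", "adaptive_contrast"),
                           ("pos", "adaptive_contrast_pos")):
            try:
                row[col] = nr.adaptive_contrast(slopes, signs=signs)
            except ValueError:
                row[col] = np.nan
        rows.append(row)
    contrasts = pd.DataFrame(rows)

    stats_report: dict = {}
    groups = contrasts["group"]
    cov = contrasts["dose_to_scan"].to_numpy()
    for col in ("adaptive_contrast", "adaptive_contrast_pos"):
        vals = contrasts[col].to_numpy()
        if np.isnan(vals).any():
            stats_report[col] = {"error": "missing contrasts for some agents"}
            continue
        stats_report[col] = {
            "raw": nr.group_adaptive_comparison(
                vals, groups, control=config.control_group,
                posthoc_alpha=config.posthoc_alpha,
            ),
            "residualized": nr.group_adaptive_comparison(
                bh.residualize(vals, cov), groups,
                control=config.control_group,
                posthoc_alpha=config.posthoc_alpha,
            ),
        }
    return pd.concat(slope_frames, ignore_index=True), contrasts, stats_report


def run_study(config: StudyConfig, seed: int, outdir) -> Path:
    """Run the full pipeline and write every artifact under ``outdir``.

    Deterministic given ``seed``; rerunning with the same seed reproduces
    byte-identical CSV outputs.  Returns the output directory.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "study.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
        config_hash = hashlib.sha256(config_yaml.encode()).hexdigest()[:16]
        logger.info("study start: seed=%s config_sha256=%s", seed, config_hash)
        (outdir / "config.yaml").write_text(config_yaml)

        records, all_trials = _simulate_cohort(config, seed)
        write_trials(all_trials, outdir / "trials.csv")
        logger.info("simulated %d agents (%d trials)", len(records),
                    len(all_trials))

        fits_frame = _fit_cohort(config, seed, records)
        fits_frame.to_csv(outdir / "fits.csv", index=False)
        comparison = compare_models(fits_frame, models=config.fit_models)
        comparison["table"].to_csv(outdir / "model_comparison.csv")
        comparison["best_by_bic"].to_csv(outdir / "best_models.csv")
        logger.info("fitted models %s; best-by-BIC counts: %s",
                    config.fit_models,
                    comparison["best_by_bic"].value_counts().to_dict())

        cohort, behavior_stats = _analyze_behavior(config, records)
        cohort.to_csv(outdir / "cohort.csv", index=False)
        (outdir / "behavior_stats.json").write_text(
            json.dumps(behavior_stats, indent=2, default=float))

        slopes, contrasts, neural_stats = _analyze_neural(config, records)
        slopes.to_csv(outdir / "neural_slopes.csv", index=False)
        contrasts.to_csv(outdir / "neural_contrasts.csv", index=False)
        (outdir / "neural_stats.json").write_text(
            json.dumps(neural_stats, indent=2, default=float))

        summary = {
            "seed": seed,
            "config_sha256": config_hash,
            "n_agents": len(records),
            "groups": {g: s.n for g, s in config.groups.items()},
            "model_comparison_dAIC_dBIC": {
                "_".join(idx): {k: v for k, v in row.items()
                                if not pd.isna(v)}
                for idx, row in comparison["table"].iterrows()
            },
            "best_by_bic": comparison["best_by_bic"].value_counts().to_dict(),
            "behavior": behavior_stats,
            "neural": neural_stats,
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, default=float))
        logger.info("study complete: artifacts in %s", outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
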