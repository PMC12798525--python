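"""End-to-end orchestration of the biomarker analysis.

Stages run in a fixed order — simulate -> preprocess -> features ->
surrogate-test -> stats -> classify — and communicate through plain-text
artifacts in the output directory, so any stage can be re-run or consumed
independently.  Every artifact carries the configuration hash and seed in
a provenance header, and re-running a stage with unchanged inputs and
configuration reproduces identical output.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import group_stats as gs
from .classification import feature_combination_sweep
from .config import PipelineConfig
from .entropy import FuzzyEnParams, MSEProfile, mean_pupil_diameter, mse_profile, participant_features
from .io import (
    read_manifest,
    read_recording,
    read_table,
    write_json_report,
    write_manifest,
    write_recording,
    write_table,
)
from .preprocessing import EpochSet, preprocess_recording
from .surrogates import surrogate_entropy_test, surrogate_mse_profile
from .synthetic import generate_cohort

__all__ = ["run_pipeline", "STAGES"]

logger = logging.getLogger("oculomse")

STAGES = ("simulate", "preprocess", "features", "surrogate-test", "stats", "classify")


def _out(config: PipelineConfig, name: str) -> Path:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return out_dir / name


def _recording_paths(config: PipelineConfig) -> list[Path]:
    rec_dir = Path(config.recordings_dir)
    if not rec_dir.is_dir():
        raise FileNotFoundError(f"recordings directory not found: {rec_dir}")
    paths = sorted(rec_dir.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no recording files (*.csv) in {rec_dir}")
    return paths


def stage_simulate(config: PipelineConfig) -> pd.DataFrame:
    """Generate the synthetic cohort and write recordings + manifest."""
    sim = config.simulation
    logger.info(
        "simulate: %d TD + %d ADHD participants, %.0f s at %.0f Hz (seed %d)",
        sim.n_td, sim.n_adhd, sim.duration_s, sim.fs_hz, sim.seed,
    )
    recordings, manifest = generate_cohort(sim)
    rec_dir = Path(config.recordings_dir)
    rec_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, rec_dir / f"{rec.participant_id}.csv", config.provenance())
    write_manifest(manifest, config.manifest_path, config.provenance())
    return manifest


def _load_epoch_sets(config: PipelineConfig) -> dict[str, EpochSet]:
    epoch_sets: dict[str, EpochSet] = {}
    for path in _recording_paths(config):
        rec = read_recording(path)
        epoch_sets[rec.participant_id] = preprocess_recording(rec, config.preprocessing)
    return epoch_sets


def stage_preprocess(config: PipelineConfig) -> pd.DataFrame:
    """Epoch-level quality-control report (exclusion statistics per participant)."""
    rows = []
    for pid, es in _load_epoch_sets(config).items():
        rows.append(
            {
                "participant_id": pid,
                "epochs_total": es.segmented_count,
                "epochs_retained": len(es.epochs),
                "epochs_excluded": es.excluded_count,
                "excluded_fraction": es.excluded_fraction,
                "mean_missing_fraction": (
                    float(np.mean([ep.missing_fraction for ep in es.epochs]))
                    if es.epochs else float("nan")
                ),
            }
        )
        logger.info(
            "preprocess %s: %d/%d epochs retained", pid,
            rows[-1]["epochs_retained"], rows[-1]["epochs_total"],
        )
    qc = pd.DataFrame(rows)
    write_table(qc, _out(config, "qc.csv"), config.provenance())
    return qc


def stage_features(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-scale MSE profiles and the participant-level feature table."""
    manifest = read_manifest(config.manifest_path)
    params = FuzzyEnParams(config.entropy.m, config.entropy.n, config.entropy.r)
    scales = config.entropy.scales
    long_rows = []
    feat_rows = []
    for pid, es in _load_epoch_sets(config).items():
        prof_h = mse_profile([ep.eye_h for ep in es.epochs], pid, "horizontal", scales, params)
        prof_v = mse_profile([ep.eye_v for ep in es.epochs], pid, "vertical", scales, params)
        pupil = mean_pupil_diameter(
            [ep.pupil_l for ep in es.epochs], [ep.pupil_r for ep in es.epochs]
        )
        for prof in (prof_h, prof_v):
            for s, tau in enumerate(prof.scales):
                long_rows.append(
                    {
                        "participant_id": pid,
                        "axis": prof.axis,
                        "scale": int(tau),
                        "fuzzyen_raw": prof.fuzzyen_raw[s],
                        "fuzzyen_log": prof.fuzzyen_log[s],
                    }
                )
        feats = participant_features(prof_h, prof_v, pupil, config.entropy.feature_scales)
        feat_rows.append({"participant_id": pid, **feats})
    mse_long = pd.DataFrame(long_rows)
    features = manifest.merge(pd.DataFrame(feat_rows), on="participant_id", how="left")
    write_table(mse_long, _out(config, "mse_long.csv"), config.provenance())
    write_table(features, _out(config, "features.csv"), config.provenance())
    return mse_long, features


def _profiles_matrix(
    mse_long: pd.DataFrame, axis: str, participants: list[str]
) -> np.ndarray:
    sub = mse_long[mse_long["axis"] == axis].pivot(
        index="participant_id", columns="scale", values="fuzzyen_log"
    )
    return sub.reindex(participants).to_numpy()


def stage_surrogate_test(config: PipelineConfig) -> pd.DataFrame:
    """Original-vs-IAAFT-surrogate nonlinearity test per group, axis and scale."""
    manifest = read_manifest(config.manifest_path)
    params = FuzzyEnParams(config.entropy.m, config.entropy.n, config.entropy.r)
    scales = config.entropy.scales
    orig: dict[str, dict[str, MSEProfile]] = {"horizontal": {}, "vertical": {}}
    surr: dict[str, dict[str, MSEProfile]] = {"horizontal": {}, "vertical": {}}
    for idx, (pid, es) in enumerate(sorted(_load_epoch_sets(config).items())):
        for axis, attr in (("horizontal", "eye_h"), ("vertical", "eye_v")):
            epochs = [getattr(ep, attr) for ep in es.epochs]
            orig[axis][pid] = mse_profile(epochs, pid, axis, scales, params)
            surr[axis][pid] = surrogate_mse_profile(
                epochs, pid, axis, scales, params,
                n_surrogates=config.surrogates.count,
                n_iterations=config.surrogates.iterations,
                seed=int(np.random.SeedSequence((config.seed, idx)).generate_state(1)[0] % 2**31),
            )
        logger.info("surrogate-test %s done", pid)

    groups = {
        "TD": manifest.loc[manifest["group"] == "TD", "participant_id"],
        "ADHD": manifest.loc[manifest["group"] == "ADHD", "participant_id"],
        "drug_naive_ADHD": manifest.loc[
            (manifest["group"] == "ADHD") & (manifest["drug_naive"] == 1),
            "participant_id",
        ],
    }
    frames = []
    for grp_name, pids in groups.items():
        pids = [p for p in pids if p in orig["horizontal"]]
        if len(pids) < 3:
            logger.warning("surrogate-test: group %s has < 3 participants, skipped", grp_name)
            continue
        for axis in ("horizontal", "vertical"):
            o = np.vstack([orig[axis][p].fuzzyen_log for p in pids])
            s = np.vstack([surr[axis][p].fuzzyen_log for p in pids])
            res = surrogate_entropy_test(o, s, np.asarray(scales), config.stats.q_levels)
            res.insert(0, "axis", axis)
            res.insert(0, "group", grp_name)
            frames.append(res)
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    write_table(table, _out(config, "surrogate_test.csv"), config.provenance())
    return table


def stage_stats(config: PipelineConfig) -> dict:
    """Group statistics: ANCOVAs, post hoc scale tests, correlations, demographics."""
    features = read_table(_out(config, "features.csv"))
    mse_long = read_table(_out(config, "mse_long.csv"))
    contrasts = {
        "td_vs_adhd": features["group"].isin(["TD", "ADHD"]),
        "td_vs_drug_naive": (features["group"] == "TD")
        | ((features["group"] == "ADHD") & (features["drug_naive"] == 1)),
    }
    report: dict = {"rm_ancova": {}, "posthoc_scale_ttests": {}, "pupil_ancova": {}}
    posthoc_frames = []
    for contrast, mask in contrasts.items():
        sub = features[mask]
        pids = sub["participant_id"].tolist()
        groups = sub["group"].to_numpy()
        age = sub["age_years"].to_numpy(dtype=float)
        for axis in ("horizontal", "vertical"):
            Y = _profiles_matrix(mse_long, axis, pids)
            try:
                res = gs.rm_ancova_group_by_scale(Y, groups, age)
            except ValueError as err:
                logger.warning("rm ANCOVA skipped (%s, %s): %s", contrast, axis, err)
                continue
            report["rm_ancova"][f"{contrast}_{axis}"] = {
                name: vars(r) for name, r in res.items()
            }
            tests = gs.posthoc_scale_ttests(
                Y, groups, np.asarray(config.entropy.scales), config.stats.q_levels
            )
            frame = pd.DataFrame([vars(t) for t in tests])
            frame.insert(0, "axis", axis)
            frame.insert(0, "contrast", contrast)
            posthoc_frames.append(frame)
            report["posthoc_scale_ttests"][f"{contrast}_{axis}"] = [
                vars(t) for t in tests
            ]
        # mean pupil diameter: one-way ANCOVA with age + post hoc t-test
        pupil = sub["pupil_size"].to_numpy(dtype=float)
        try:
            anc = gs.ancova_oneway(pupil, groups, age)
            ok = np.isfinite(pupil)
            t_res = gs.stats.ttest_ind(
                pupil[ok & (groups == "TD")], pupil[ok & (groups == "ADHD")],
                equal_var=True,
            )
            report["pupil_ancova"][contrast] = {
                **vars(anc),
                "posthoc_t": float(t_res.statistic),
                "posthoc_p": float(t_res.pvalue),
            }
        except ValueError as err:
            logger.warning("pupil ANCOVA skipped (%s): %s", contrast, err)

    correlations = gs.correlate_with_severity(features)
    report["severity_correlations"] = correlations.to_dict(orient="records")
    defined = correlations[correlations["defined"]]
    if not defined.empty:
        r_star = float(defined.loc[defined["r"].abs().idxmax(), "r"])
        if 0 < abs(r_star) < 1:
            report["power_analysis"] = {
                "r": r_star,
                "alpha": config.stats.alpha,
                "power": 0.80,
                **gs.required_sample_size_correlation(r_star, config.stats.alpha, 0.80),
            }
    demo = gs.demographics_table(features)
    report["demographics"] = demo.to_dict(orient="records")

    if posthoc_frames:
        write_table(
            pd.concat(posthoc_frames, ignore_index=True),
            _out(config, "posthoc_scale_ttests.csv"), config.provenance(),
        )
    write_table(demo, _out(config, "demographics.csv"), config.provenance())
    write_table(correlations, _out(config, "severity_correlations.csv"), config.provenance())
    write_json_report(report, _out(config, "stats.json"), config.provenance())
    return report


def stage_classify(config: PipelineConfig) -> dict:
    """Feature-combination sweep of the weighted lasso classifier, both contrasts."""
    features = read_table(_out(config, "features.csv"))
    report: dict = {}
    sweep_rows = []
    contrasts = {
        "td_vs_adhd": features,
        "td_vs_drug_naive": features[
            (features["group"] == "TD")
            | ((features["group"] == "ADHD") & (features["drug_naive"] == 1))
        ],
    }
    for contrast, table in contrasts.items():
        counts = table.groupby("group")["participant_id"].count()
        if counts.size < 2 or counts.min() < 3:
            logger.warning("classify: contrast %s has too few participants, skipped", contrast)
            continue
        reports = feature_combination_sweep(table, config=config.cv)
        report[contrast] = {
            "+".join(fs): rep.to_dict() for fs, rep in reports.items()
        }
        for fs, rep in reports.items():
            sweep_rows.append(
                {
                    "contrast": contrast,
                    "features": "+".join(fs),
                    "n_features": len(fs),
                    "auc_roc": rep.auc_roc,
                    "auc_pr": rep.auc_pr,
                    "f1": rep.f1,
                    "threshold": rep.threshold,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                }
            )
    write_table(pd.DataFrame(sweep_rows), _out(config, "classification_sweep.csv"), config.provenance())
    write_json_report(report, _out(config, "classification.json"), config.provenance())
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "features": stage_features,
    "surrogate-test": stage_surrogate_test,
    "stats": stage_stats,
    "classify": stage_classify,
}


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] = STAGES
) -> dict[str, object]:
    """Run the requested stages in canonical order.

    Preconditions of all requested stages are checked before anything runs,
    so a missing input fails cleanly without partial outputs.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; valid stages: {list(STAGES)}")
    ordered = [s for s in STAGES if s in stages]

    if "simulate" not in ordered:
        needs_recordings = any(
            s in ordered for s in ("preprocess", "features", "surrogate-test")
        )
        if needs_recordings:
            _recording_paths(config)  # raises with the offending path
            if not Path(config.manifest_path).exists():
                raise FileNotFoundError(f"manifest not found: {config.manifest_path}")
    if "features" not in ordered and any(s in ordered for s in ("stats", "classify")):
        for artifact in ("features.csv",) + (("mse_long.csv",) if "stats" in ordered else ()):
            if not (Path(config.output_dir) / artifact).exists():
                raise FileNotFoundError(
                    f"required artifact missing: {Path(config.output_dir) / artifact} "
                    "(run the 'features' stage first)"
                )

    results = {}
    for stage in ordered:
        logger.info("=== stage %s ===", stage)
        results[stage] = _STAGE_FUNCS[stage](config)
    return results
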