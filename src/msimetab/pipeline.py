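"""End-to-end orchestration: simulate -> process -> analyze.

Ties the stages into reproducible runs on a dataset directory:

``simulate`` writes a synthetic study (manifest, ground truth, glucose
curves, raw multiplexed traces for the study runs and the triplicate
dilution-screen runs).  ``process`` inverts the traces into an assigned
peak table, applies the dilution trend filter and the study-level
detection/precision filter, and writes the curated feature matrix.
``analyze`` runs the cohort arithmetic, the metabolite statistics and the
prognostic regression, and writes a single summary JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import feature_qc, glucose, processing, prognostic, stats_suite
from . import synthetic
from .config import PipelineConfig
from .study_design import (StudyManifest, build_manifest,
                           load_cohort_table, records_to_frame)

log = logging.getLogger("msimetab")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def simulate_dataset(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate a full synthetic study under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = build_manifest(config.n_subjects, config.timepoints,
                              config.states)
    panel = synthetic.default_panel(config.n_features)
    universe = (synthetic.make_feature_universe(panel)
                if config.with_feature_universe else panel)
    noise = synthetic.NoiseConfig(cv_analytical=config.cv_analytical,
                                  cv_biological_default=config.cv_biological)
    truth = synthetic.simulate_cohort(manifest, universe, noise,
                                      seed=config.seed)
    shape = synthetic.PeakShapeConfig(baseline_sd=config.baseline_sd)
    rng = np.random.default_rng(config.seed + 1)

    (out / "manifest.json").write_text(manifest.to_json())
    truth.concentrations.to_csv(out / "truth.csv", index=False)
    truth.qc_responses.to_csv(out / "qc_truth.csv", index=False)
    truth.glucose_frame().to_csv(out / "glucose.csv", index=False)
    (out / "config.json").write_text(config.to_json())

    runs_dir = out / "runs"
    for rid in manifest.run_ids:
        responses = synthetic.run_segment_responses(truth, manifest, rid)
        trace = synthetic.synthesize_run(
            rid, responses, universe, config=shape,
            rng=rng if config.baseline_sd > 0 else None)
        trace.save(runs_dir)
        log.info("simulate: wrote run %s (%d channels)", rid,
                 len(trace.channels))

    dil_dir = out / "dilution"
    dil_responses = synthetic.dilution_segment_responses(universe)
    for rep in range(1, config.dilution_replicates + 1):
        trace = synthetic.synthesize_run(
            f"dil{rep:02d}", dil_responses, universe, config=shape,
            rng=rng if config.baseline_sd > 0 else None)
        trace.save(dil_dir)
    log.info("simulate: dataset at %s (%d study runs, %d dilution runs)",
             out, manifest.n_runs, config.dilution_replicates)
    return out


# ---------------------------------------------------------------------------
# process
# ---------------------------------------------------------------------------

def _load_manifest(path: Path) -> tuple[dict, dict]:
    """Segment metadata maps from a manifest.json."""
    payload = json.loads(path.read_text())
    segment_samples: dict[tuple[str, int], dict] = {}
    for rid, segments in payload["runs"].items():
        for seg in segments:
            segment_samples[(rid, seg["segment_index"])] = {
                "subject": seg["subject_id"],
                "timepoint": seg["timepoint"],
                "state": seg["training_state"],
                "is_qc": seg["is_qc"],
                "run_id": rid,
            }
    return payload, segment_samples


def process_dataset(dataset_dir: str | Path, config: PipelineConfig,
                    out_dir: str | Path | None = None) -> dict:
    """Traces to curated feature matrix; returns stage artifacts.

    Stages and their feature counts are logged so a run shows the
    universe -> dilution-screen -> redundancy -> study-filter narrowing.
    """
    dataset = Path(dataset_dir)
    out = Path(out_dir) if out_dir else dataset / "processed"
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = dataset / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{dataset}: no manifest.json")
    _, segment_samples = _load_manifest(manifest_path)

    window = tuple(config.window_s)
    kw = dict(min_height=config.min_height, snr_min=config.snr_min,
              window=window, spacing_tol=config.spacing_tol)

    study_tables = []
    for path in sorted((dataset / "runs").glob("*.csv")):
        study_tables.append(
            processing.process_run(synthetic.RawTrace.load(path), **kw))
    if not study_tables:
        raise FileNotFoundError(f"{dataset}: no study run traces")
    dil_tables = []
    for path in sorted((dataset / "dilution").glob("*.csv")):
        dil_tables.append(
            processing.process_run(synthetic.RawTrace.load(path), **kw))

    # global feature keys (m/z + RMT cluster) so dilution and study runs
    # agree on feature identity
    n_study = sum(len(t) for t in study_tables)
    all_tables = processing.assign_feature_keys(
        pd.concat(study_tables + dil_tables, ignore_index=True))
    study_keyed = all_tables.iloc[:n_study]
    dil_keyed = all_tables.iloc[n_study:]
    n_universe = all_tables["key"].nunique()
    log.info("process: %d raw features detected", n_universe)

    # dilution trend screen
    dil_verdicts = []
    dil_kept = set(all_tables["key"].unique())
    if dil_tables:
        dil_kept, dil_verdicts = dilution_screen(dil_keyed, config)
        log.info("process: dilution trend filter kept %d / %d features",
                 len(dil_kept), n_universe)

    # redundancy rejection on run-level features
    feat_summary = (all_tables.groupby("key")
                    .agg(mz=("mz", "median"), rmt=("rmt", "median"),
                         response=("rpa", "median")))
    kept_triples, _ = processing.reject_redundant(
        [(r.mz, r.rmt, r.response) for r in feat_summary.itertuples()])
    kept_pairs = {(round(mz, 4), round(rmt, 3)) for mz, rmt, _ in kept_triples}
    nonredundant = {
        k for k in feat_summary.index
        if (round(feat_summary.loc[k, "mz"], 4),
            round(feat_summary.loc[k, "rmt"], 3)) in kept_pairs}
    log.info("process: redundancy rejection kept %d / %d features",
             len(nonredundant), n_universe)

    matrix = feature_qc.build_feature_matrix(study_keyed, segment_samples)
    screened = [k for k in matrix.feature_keys
                if k in dil_kept and k in nonredundant]
    matrix = matrix.subset(screened)

    curated, study_verdicts = feature_qc.study_filter(
        matrix, config.min_detect_frac, config.qc_cv_max)
    log.info("process: study filter kept %d / %d features",
             len(curated.feature_keys), len(screened))
    qc_report = feature_qc.qc_monitor(curated)
    log.info("process: mean QC CV %.3f", qc_report.mean_cv)

    curated.to_csv(out / "feature_matrix.csv")
    if dil_verdicts:
        feature_qc.verdicts_to_frame(dil_verdicts).to_csv(
            out / "dilution_verdicts.csv", index=False)
    feature_qc.verdicts_to_frame(study_verdicts).to_csv(
        out / "study_verdicts.csv", index=False)
    (out / "qc_report.json").write_text(json.dumps({
        "mean_qc_cv": qc_report.mean_cv,
        "per_feature_cv": {k: float(v) for k, v in
                           qc_report.per_feature_cv.items()},
        "counts": {"universe": n_universe,
                   "after_dilution_screen": len(dil_kept),
                   "after_redundancy": len(nonredundant),
                   "final": len(curated.feature_keys)},
    }, indent=1))
    return {"matrix": curated, "qc_report": qc_report,
            "dilution_verdicts": dil_verdicts,
            "study_verdicts": study_verdicts, "out": out}


def dilution_screen(dil_keyed: pd.DataFrame, config: PipelineConfig):
    """Run the dilution trend filter on keyed dilution-run peak rows."""
    levels = np.asarray(synthetic.DILUTION_LEVELS)
    run_ids = sorted(dil_keyed["run_id"].unique())
    rep_index = {rid: i for i, rid in enumerate(run_ids)}
    kept = set()
    verdicts = []
    for key, grp in dil_keyed.groupby("key"):
        resp = np.full((levels.size, len(run_ids)), np.nan)
        for row in grp.itertuples():
            resp[row.segment - 1, rep_index[row.run_id]] = row.rpa
        series = feature_qc.DilutionSeries(key, levels, resp)
        verdict = feature_qc.dilution_trend_filter(
            series, config.cv_max, config.r2_min, config.min_levels)
        verdicts.append(verdict)
        if verdict.kept:
            kept.add(key)
    return kept, verdicts


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def analyze(
    config: PipelineConfig,
    matrix: feature_qc.FeatureMatrix | None = None,
    glucose_curves: dict | None = None,
    cohort_records=None,
    out_dir: str | Path | None = None,
) -> dict:
    """Cohort arithmetic, metabolite statistics and prognostic regression.

    Any of the inputs may be absent; stages without their inputs are
    skipped with a notice and the summary records what ran.
    """
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": []}

    if cohort_records is None:
        cohort_records = load_cohort_table()
    deltas = glucose.cohort_deltas(cohort_records)
    frame = records_to_frame(cohort_records)
    outlier = glucose.grubbs_test(frame["d_tauc"], alpha=config.alpha)
    excl = (frame.drop(frame.index[outlier.flagged_index])
            if outlier.flagged_index is not None else frame)
    calls, counts = glucose.classify_responders(
        frame["d_p2hg"], -config.responder_thresh, config.responder_thresh)
    summary["cohort"] = {
        "n_subjects": int(len(frame)),
        "mean_deltas": {k: float(v) for k, v in deltas["mean"].items()},
        "sd_deltas": {k: float(v) for k, v in deltas["sd"].items()},
        "p_paired_d_vo2max": glucose.paired_t_test(frame["d_vo2max"]).p,
        "grubbs_d_tauc": {"G": outlier.statistic_g,
                          "G_crit": outlier.critical_g,
                          "flagged": (frame.index[outlier.flagged_index]
                                      if outlier.flagged_index is not None
                                      else None)},
        "mean_d_tauc_outlier_excluded": float(excl["d_tauc"].mean()),
        "responders": counts,
        "r2_d_p2hg_vs_d_tauc": glucose.pearson_r2(frame["d_p2hg"],
                                                  frame["d_tauc"]),
    }
    summary["stages"].append("cohort")

    d_p2hg = None
    if glucose_curves:
        rows = []
        for (subj, state), curve in sorted(glucose_curves.items()):
            m = glucose.compute_metrics(curve,
                                        end_min=max(config.timepoints))
            rows.append({"subject": subj, "state": state, "fg": m.fg,
                         "p2hg": m.p2hg, "tauc": m.tauc})
        gdf = pd.DataFrame(rows).set_index(["subject", "state"])
        states = config.states
        if len(states) == 2:
            naive = gdf.xs(states[0], level="state")
            trained = gdf.xs(states[1], level="state")
            d_p2hg = (trained["p2hg"] - naive["p2hg"]).rename("d_p2hg")
            _, sim_counts = glucose.classify_responders(
                d_p2hg, -config.responder_thresh, config.responder_thresh)
            summary["glucose"] = {
                "mean_d_p2hg": float(d_p2hg.mean()),
                "mean_d_tauc": float((trained["tauc"]
                                      - naive["tauc"]).mean()),
                "responders": sim_counts,
            }
            summary["stages"].append("glucose")
        if out:
            gdf.to_csv(out / "glucose_metrics.csv")

    if matrix is None or not matrix.feature_keys:
        summary["notice"] = "no feature matrix supplied; metabolite " \
            "statistics and prognostic model skipped"
        log.info("analyze: %s", summary["notice"])
        if out:
            (out / "summary.json").write_text(
                json.dumps(summary, indent=1, default=str))
        return summary

    tm = stats_suite.preprocess(matrix)
    meta = matrix.meta
    study_mask = ~matrix.qc_mask
    study_tm = tm.values.loc[study_mask]
    study_meta = meta.loc[study_mask]
    m_family = config.bonferroni_family or len(matrix.feature_keys)

    anova_rows = []
    try:
        anova_rows = stats_suite.rm_anova2(study_tm, study_meta,
                                           m_features=m_family,
                                           alpha=config.alpha)
        n_time = sum(r.p_adj_time < config.alpha for r in anova_rows)
        n_train = sum(r.p_adj_training < config.alpha for r in anova_rows)
        summary["anova"] = {"n_significant_time": n_time,
                            "n_significant_training": n_train}
        summary["stages"].append("anova")
    except stats_suite.AnalysisError as exc:
        summary["anova_error"] = str(exc)
        log.warning("analyze: ANOVA skipped: %s", exc)

    t0, t_end = min(config.timepoints), max(config.timepoints)
    sub0 = matrix.meta["timepoint"].isin([t0, t_end]) | matrix.qc_mask
    anchor = feature_qc.FeatureMatrix(meta.loc[sub0].reset_index(drop=True),
                                      matrix.values.loc[sub0].reset_index(drop=True))
    volcano_time = stats_suite.volcano_paired(
        anchor, "timepoint", t_end, t0, config.fc_thresh, config.p_thresh)
    summary["volcano_time_significant"] = sum(
        r.significant for r in volcano_time)

    # per-feature ROC for the post-prandial contrast (t_end vs t0)
    roc_rows = []
    logged = np.log10(matrix.values.where(matrix.values > 0))
    for key in matrix.feature_keys:
        case = logged.loc[study_mask & (meta["timepoint"] == t_end), key].dropna()
        ctrl = logged.loc[study_mask & (meta["timepoint"] == t0), key].dropna()
        if len(case) and len(ctrl):
            roc_rows.append(stats_suite.roc_auc(case, ctrl, label=key))
    roc_rows.sort(key=lambda r: -r.auc)
    summary["top_roc_time"] = [
        {"feature": r.label, "auc": r.auc, "p": r.p} for r in roc_rows[:5]]
    summary["stages"].append("roc")

    scores, explained = stats_suite.pca_scores(tm, config.n_components)
    summary["pca_explained"] = [float(e) for e in explained]
    if out:
        feature_qc.verdicts_to_frame(anova_rows).to_csv(
            out / "anova.csv", index=False)
        feature_qc.verdicts_to_frame(volcano_time).to_csv(
            out / "volcano_time.csv", index=False)
        scores.to_csv(out / "pca_scores.csv")
        tree = stats_suite.hca(tm, labels=[
            f"{s}|{t}|{st}" if not q else f"QC|{r}"
            for s, t, st, q, r in meta.itertuples(index=False)])
        (out / "hca.nwk").write_text(tree.to_newick())

    # prognostic model from the naive state at the anchor timepoints
    if d_p2hg is not None and len(config.states) == 2:
        naive_mask = (meta["state"] == config.states[0]) | matrix.qc_mask
        naive_matrix = feature_qc.FeatureMatrix(
            meta.loc[naive_mask].reset_index(drop=True),
            matrix.values.loc[naive_mask].reset_index(drop=True))
        candidates = [r.label for r in roc_rows[:config.n_candidates]]
        try:
            panel = prognostic.build_panel(naive_matrix, candidates,
                                           t0=t0, t_end=t_end)
            model = prognostic.stepwise_select(panel, d_p2hg,
                                              max_vars=config.max_vars)
            summary["prognostic"] = model.to_dict()
            summary["stages"].append("prognostic")
            if out:
                (out / "prognostic_model.json").write_text(
                    json.dumps(model.to_dict(), indent=1))
                obs_pred = pd.DataFrame({
                    "observed": d_p2hg,
                    "predicted_loocv": model.loocv_predictions})
                obs_pred.to_csv(out / "observed_vs_predicted.csv")
        except (prognostic.PanelError,
                prognostic.RankDeficiencyError) as exc:
            summary["prognostic_error"] = str(exc)
            log.warning("analyze: prognostic model skipped: %s", exc)

    if out:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, default=str))
    return summary
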