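"""End-to-end pipeline orchestration.

Stage order: threshold comparison on global binary features, threshold
selection, consensus-labelled augmentation, feature extraction at the
selected threshold, ML and GNN cross-validation, biomarker discovery
(RLF + SpeCo), and model explanations.  The run is a pure function of
(config, cohort, seeds): identical inputs produce identical artifacts.
Every stage writes its tables before the next starts, so a failing stage
leaves partial outputs behind an exception naming the stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import biomarkers as bm
from . import explain as ex
from .augmentation import balance_cohort
from .config import PipelineConfig
from .datamodel import Cohort, ConnectomlError
from .features import feature_table, global_measure_names, measure_names
from .gnn import GnnConfig, crossval_gnn, make_gnn, cohort_samples, train as gnn_train
from .ml import EVAL_MODELS, fit_eval, summarize_runs
from .thresholds import select_threshold, sweep_thresholds


class StageError(ConnectomlError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineReport:
    selected_tau: float
    threshold_metrics: pd.DataFrame
    ml_metrics: pd.DataFrame
    gnn_metrics: pd.DataFrame
    rlf_top_pairs: list
    roi_frequency: pd.Series
    speco_settings: list
    shap_percent: pd.Series
    gnn_feature_rank: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path)


def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort,
    out_dir: str | Path | None = None,
    gnn_config: GnnConfig | None = None,
    n_explain: int = 10,
) -> PipelineReport:
    out = Path(out_dir) if out_dir is not None else None
    if gnn_config is None:
        gnn_config = GnnConfig(seed=config.seed_for("gnn"))
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                          default=str))

    # -- threshold comparison & selection ---------------------------------
    stage = "thresholds"
    try:
        table = sweep_thresholds(cohort, config.tau_grid, folds=config.folds,
                                 seed=config.seed_for(stage))
        tau = select_threshold(table)
        if out is not None:
            _write(table, out / "threshold_metrics.csv")
            (out / "selected_tau.json").write_text(json.dumps({"tau": tau}))
        record(stage, selected_tau=tau)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- augmentation ------------------------------------------------------
    stage = "augment"
    try:
        augmented = balance_cohort(
            cohort, tau=tau, n_pairs=config.n_pairs,
            noise_lo=config.noise_lo, noise_hi=config.noise_hi,
            target_ratio=config.balance_ratio, seed=config.seed_for(stage))
        record(stage, n_before=len(cohort), n_after=len(augmented))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- features at the selected threshold -------------------------------
    stage = "features"
    try:
        tables = feature_table(augmented, tau, scope="both")
        if out is not None:
            _write(tables.global_df, out / "features_global.csv")
            _write(tables.local_df, out / "features_local.csv")
        record(stage, tau=tau, n_subjects=len(augmented))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    original_mask = np.array([s.provenance == "original" for s in augmented])
    y = tables.labels

    # -- classical ML ------------------------------------------------------
    stage = "ml"
    try:
        Xg = tables.global_df[global_measure_names()].to_numpy()
        Xg = np.nan_to_num(Xg, nan=0.0, posinf=0.0, neginf=0.0)
        summaries = [
            fit_eval(Xg, y, name, folds=config.folds,
                     seed=config.seed_for(f"ml-{name}"),
                     original_mask=original_mask)
            for name in EVAL_MODELS
        ]
        ml_metrics = summarize_runs(summaries)
        if out is not None:
            _write(ml_metrics, out / "ml_metrics.csv")
        record(stage, models=list(EVAL_MODELS))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- GNNs --------------------------------------------------------------
    stage = "gnn"
    try:
        n_roi = augmented.n_roi
        local = tables.local_df.to_numpy().reshape(len(augmented), n_roi, -1)
        gnn_summaries = [
            crossval_gnn(augmented, kind, folds=config.folds,
                         config=replace(gnn_config,
                                        seed=config.seed_for(f"gnn-{kind}")),
                         tau=tau, local_features=local)
            for kind in ("gcn", "dgcnn")
        ]
        gnn_metrics = summarize_runs(gnn_summaries)
        if out is not None:
            _write(gnn_metrics, out / "gnn_metrics.csv")
        record(stage, models=["gcn", "dgcnn"])
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- biomarkers --------------------------------------------------------
    stage = "biomarkers"
    try:
        orig = augmented.originals()
        orig_tables = tables.local_df[original_mask]
        finite = np.isfinite(orig_tables.to_numpy(dtype=float)).all(axis=0)
        local_finite = orig_tables.loc[:, finite]
        scored = bm.rlf_scores(local_finite, orig.labels, method="univariate")
        top = bm.rlf_select(scored, top_m=min(config.rlf_top_m, len(scored)))
        freq = bm.roi_frequency(top)
        settings = bm.speco(orig, k_range=config.speco_k_range,
                            theta_range=config.speco_theta_range,
                            seed=config.seed_for("speco"))
        if out is not None:
            pd.DataFrame([{"roi_id": p.roi_id, "measure": p.measure,
                           "score": p.score} for p in top]
                         ).to_csv(out / "rlf_top_pairs.csv", index=False)
            freq.rename("count").to_csv(out / "roi_frequency.csv")
            speco_json = [
                {"k": s.k, "theta": s.theta,
                 "informative": [{"i": i, "j": j, "group": g}
                                 for (i, j), g in sorted(s.informative.items())]}
                for s in settings
            ]
            (out / "speco_report.json").write_text(json.dumps(speco_json, indent=2))
        record(stage, n_rlf=len(top), n_speco_settings=len(settings))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # -- explanations ------------------------------------------------------
    stage = "explain"
    try:
        rf = RandomForestClassifier(n_estimators=50, max_depth=5,
                                    random_state=config.seed_for("explain"))
        Xo = Xg[original_mask]
        yo = y[original_mask]
        rf.fit(Xo, yo)
        attr = ex.feature_attribution(rf, Xo, mode="exact",
                                      feature_names=global_measure_names())
        shap_pct = ex.importance_percentages(attr.mean_abs_series()).sort_values(
            ascending=False)
        # explain a small GCN trained on the full cohort
        samples = cohort_samples(augmented, tau, local_features=local)
        for s in samples:
            s.X = np.nan_to_num(s.X, nan=0.0)
        rng = np.random.default_rng(config.seed_for("explain-gnn"))
        idx = rng.permutation(len(samples))
        n_val = max(2, len(samples) // 10)
        val = [samples[i] for i in idx[:n_val]]
        tr = [samples[i] for i in idx[n_val:]]
        model = make_gnn("gcn", samples[0].X.shape[1], gnn_config)
        params, _ = gnn_train(model, tr, val, gnn_config)
        subset = samples[: min(n_explain, len(samples))]
        mask, _ = ex.gnn_explain_cohort(model, params, subset,
                                        labels=y[: len(subset)],
                                        seed=config.seed_for("explain-mask"))
        from .features import local_measure_names

        rank = ex.rank_explained_features(
            pd.Series(mask, index=local_measure_names()))
        if out is not None:
            shap_pct.rename("percent").to_csv(out / "shap_percent.csv")
            _write(rank, out / "gnn_feature_rank.csv")
        record(stage, n_explained=len(subset))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    return PipelineReport(
        selected_tau=tau,
        threshold_metrics=table,
        ml_metrics=ml_metrics,
        gnn_metrics=gnn_metrics,
        rlf_top_pairs=top,
        roi_frequency=freq,
        speco_settings=settings,
        shap_percent=shap_pct,
        gnn_feature_rank=rank,
        manifest=manifest,
    )
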