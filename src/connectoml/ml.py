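"""Classical classification of global graph features.

Five evaluation models (AdaBoost, Decision Tree, KNN, SVM, Logistic
Regression) are scored with stratified k-fold cross-validation, an inner
grid search, and a standardization + min-max normalization pipeline fitted
on training folds only.  Random Forest and XGBoost are reserved for
labelling augmented subjects and are excluded from evaluation by an
allow-list, so consensus labels never bias the reported metrics.
Augmented subjects may appear in training folds but never in test folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .datamodel import ConnectomlError

METRIC_NAMES = ("accuracy", "specificity", "sensitivity", "precision", "f1")

#: models allowed in evaluation (labeler models are deliberately absent)
EVAL_MODELS = ("adaboost", "decision_tree", "knn", "svm", "logistic_regression")
#: models used to label augmented data and to compare binarization thresholds
LABELER_MODELS = ("random_forest", "xgboost")
THRESHOLD_MODELS = ("random_forest", "xgboost", "adaboost")


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """The five study metrics from a binary confusion table.

    Sensitivity is recall on the patient class (label 1), specificity recall
    on controls.  Precision with an empty predicted-positive set is 0.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ConnectomlError("confusion counts must be nonnegative")
    if tp + fn == 0 or tn + fp == 0:
        raise ConnectomlError("confusion table lacks one true class entirely")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    acc = (tp + tn) / (tp + fn + tn + fp)
    f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    return {"accuracy": acc, "specificity": spec, "sensitivity": sens,
            "precision": prec, "f1": f1}


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    return tp, fn, tn, fp


DEFAULT_GRIDS: dict[str, dict] = {
    "adaboost": {"model__n_estimators": [50, 100]},
    "decision_tree": {"model__max_depth": [3, 5, None],
                      "model__min_samples_leaf": [1, 3]},
    "knn": {"model__n_neighbors": [3, 5, 7]},
    "svm": {"model__C": [0.5, 1.0, 5.0], "model__kernel": ["rbf", "linear"]},
    "logistic_regression": {"model__C": [0.1, 1.0, 10.0]},
    "random_forest": {"model__n_estimators": [100], "model__max_depth": [None, 5]},
    "xgboost": {"model__n_estimators": [100], "model__max_depth": [3, 5]},
}


def make_model(name: str, seed: int = 0):
    """Instantiate a model by registry name (seeded where stochastic)."""
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "knn":
        return KNeighborsClassifier()
    if name == "svm":
        return SVC(random_state=seed)
    if name == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if name == "xgboost":
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             tree_method="hist", eval_metric="logloss")
    raise ConnectomlError(f"unknown model {name!r}")


def make_pipeline(name: str, seed: int = 0) -> Pipeline:
    return Pipeline([
        ("standardize", StandardScaler()),
        ("normalize", MinMaxScaler()),
        ("model", make_model(name, seed)),
    ])


@dataclass
class MetricSummary:
    """Per-model cross-validation summary (fraction scale internally)."""

    model: str
    mean: dict[str, float]
    std: dict[str, float]
    per_fold: list[dict[str, float]] = field(default_factory=list)


def fit_eval(
    X: np.ndarray,
    y: np.ndarray,
    model_name: str,
    folds: int = 10,
    grid: dict | None = None,
    seed: int = 0,
    original_mask: np.ndarray | None = None,
    allow_labelers: bool = False,
) -> MetricSummary:
    """Outer stratified k-fold with inner grid search; five metrics per fold.

    ``original_mask`` marks non-augmented subjects: only they are eligible
    for test folds; augmented subjects are appended to every training fold.
    """
    allowed = EVAL_MODELS + (THRESHOLD_MODELS if allow_labelers else ())
    if model_name not in allowed:
        raise ConnectomlError(
            f"model {model_name!r} is not on the evaluation allow-list"
        )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if original_mask is None:
        original_mask = np.ones(len(y), dtype=bool)
    orig_idx = np.flatnonzero(original_mask)
    aug_idx = np.flatnonzero(~original_mask)
    y_orig = y[orig_idx]
    counts = np.bincount(y_orig, minlength=2)
    if counts.min() < folds:
        raise ConnectomlError(
            f"need at least {folds} original subjects per class, got {counts.tolist()}"
        )
    grid = DEFAULT_GRIDS.get(model_name, {}) if grid is None else grid
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    for tr, te in cv.split(np.zeros(len(orig_idx)), y_orig):
        train = np.concatenate([orig_idx[tr], aug_idx]).astype(int)
        test = orig_idx[te]
        pipe = make_pipeline(model_name, seed)
        if grid:
            inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
            est = GridSearchCV(pipe, grid, cv=inner, scoring="accuracy", n_jobs=1)
        else:
            est = pipe
        est.fit(X[train], y[train])
        pred = est.predict(X[test])
        per_fold.append(metrics_from_confusion(*confusion_counts(y[test], pred)))
    mean = {m: float(np.mean([f[m] for f in per_fold])) for m in METRIC_NAMES}
    std = {m: float(np.std([f[m] for f in per_fold])) for m in METRIC_NAMES}
    return MetricSummary(model=model_name, mean=mean, std=std, per_fold=per_fold)


def summarize_runs(summaries: list[MetricSummary]) -> pd.DataFrame:
    """Report table with 'mean ± std' cells on the percent scale."""
    if not summaries:
        raise ConnectomlError("no summaries to report")
    rows = {}
    for s in summaries:
        row = {}
        for m in METRIC_NAMES:
            if m in s.mean and np.isfinite(s.mean[m]):
                row[m] = f"{100 * s.mean[m]:.1f} ± {100 * s.std[m]:.1f}"
            else:
                row[m] = "—"
        rows[s.model] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_NAMES))
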