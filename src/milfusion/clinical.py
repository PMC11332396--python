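"""Random-forest and SVM recurrence models over the clinicopathological covariates.

Eight human-assessed factors are available: pathological T, depth of
invasion (DOI, mm), lymphatic / vascular / perineural invasion, age, sex
and tumour side, used as nested factor sets ("two", "five", "eight").
Model selection is an exhaustive grid search over stratified 10-fold
cross-validation, selecting the grid point with the highest mean AUC (ties
broken by declared grid order).  SVM features are standardized with
training-fold statistics only and probabilities come from Platt-type
sigmoid calibration; random-forest probabilities are tree-vote fractions
on raw features.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluation import auc, threshold_metrics, UndefinedMetricError
from .synthetic import ClinicalRecord

__all__ = ["FEATURE_SETS", "GridSpec", "ClinicalModel", "encode_features",
           "stratified_folds", "grid_search_cv", "fit", "predict_proba",
           "default_grid"]

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "two": ("pT", "doi_mm"),
    "five": ("pT", "doi_mm", "ly", "v", "pn"),
    "eight": ("pT", "doi_mm", "ly", "v", "pn", "age", "sex", "side"),
}

_FIELD_OF_COLUMN = {
    "pT": "pT", "doi_mm": "doi_mm", "ly": "lymphatic_invasion",
    "v": "vascular_invasion", "pn": "perineural_invasion",
    "age": "age", "sex": "sex", "side": "side",
}


@dataclass(frozen=True)
class GridSpec:
    """An exhaustive hyperparameter grid for one model family.

    ``grid`` maps parameter names to candidate lists; points are enumerated
    in the declared (row-major) order, which also defines tie-breaking.
    """

    model_family: str            # "RF" or "SVM"
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self):
        if self.model_family not in ("RF", "SVM"):
            raise ValueError(f"unknown model_family: {self.model_family}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("grid must be non-empty")

    def points(self) -> list[dict]:
        keys = list(self.grid)
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]


def default_grid(model_family: str) -> GridSpec:
    """Small exhaustive default grids spanning conventional ranges."""
    if model_family == "RF":
        return GridSpec("RF", {
            "n_estimators": [100, 300, 500],
            "max_depth": [2, 4, None],
            "min_samples_leaf": [1, 3],
        })
    if model_family == "SVM":
        return GridSpec("SVM", {
            "kernel": ["linear", "rbf"],
            "C": [0.1, 1, 10, 100],
            "gamma": ["scale", 0.01, 0.1],
        })
    raise ValueError(f"unknown model_family: {model_family}")


@dataclass
class ClinicalModel:
    model_family: str
    feature_set: str
    hyperparameters: dict
    estimator: object = None     # fitted sklearn estimator / pipeline

    def __post_init__(self):
        if self.model_family not in ("RF", "SVM"):
            raise ValueError(f"unknown model_family: {self.model_family}")


def encode_features(records: Sequence[ClinicalRecord], feature_set: str) -> np.ndarray:
    """Numeric design matrix in the fixed column order of the feature set.

    pT stays {1,2}; booleans become {0,1}; sex M->0 / F->1; side left->0 /
    right->1; doi_mm and age are used as-is.  A missing (None/NaN) value
    raises an error naming the case and field.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature_set: {feature_set!r}")
    cols = FEATURE_SETS[feature_set]
    rows = []
    for rec in records:
        row = []
        for col in cols:
            value = getattr(rec, _FIELD_OF_COLUMN[col])
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise ValueError(f"case {rec.case_id}: missing value for {col}")
            if col == "sex":
                value = {"M": 0, "F": 1}[value]
            elif col == "side":
                value = {"left": 0, "right": 1}[value]
            elif col in ("ly", "v", "pn"):
                value = int(value)
            row.append(float(value))
        rows.append(row)
    return np.asarray(rows, dtype=float)


def stratified_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1 per case) with per-fold class counts within
    one of perfect proportionality."""
    labels = np.asarray(labels).astype(int)
    for cls in np.unique(labels):
        if (labels == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} cases")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[test_idx] = fold
    return assignment


def _make_estimator(family: str, params: dict, seed: int):
    if family == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    pipeline_params = dict(params)
    if pipeline_params.get("kernel") == "linear":
        pipeline_params.pop("gamma", None)
    # Platt-type sigmoid calibration fitted within the training data only;
    # features standardized with training statistics via the pipeline
    svc = SVC(random_state=seed, **pipeline_params)
    return Pipeline([
        ("scale", StandardScaler()),
        ("svc", CalibratedClassifierCV(svc, method="sigmoid", ensemble=False)),
    ])


def fit(X: np.ndarray, y, model_family: str, hyperparameters: dict,
        seed: int = 0, feature_set: str = "") -> ClinicalModel:
    est = _make_estimator(model_family, hyperparameters, seed)
    est.fit(np.asarray(X, dtype=float), np.asarray(y).astype(int))
    return ClinicalModel(model_family=model_family, feature_set=feature_set,
                         hyperparameters=dict(hyperparameters), estimator=est)


def predict_proba(model: ClinicalModel, X: np.ndarray) -> np.ndarray:
    """Probability of recurrence per case, in [0,1]."""
    if model.estimator is None:
        raise RuntimeError("predict before fit: model has no fitted estimator")
    return model.estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]


def grid_search_cv(X: np.ndarray, y, grid: GridSpec, folds: np.ndarray,
                   seed: int = 0) -> tuple[dict, pd.DataFrame]:
    """Evaluate every grid point on the given fold assignment; return the
    winner (max mean AUC, ties to the earlier declared point) and its
    per-fold metrics.

    Folds whose held-out part is single-class have undefined AUC and are
    excluded with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    folds = np.asarray(folds)
    fold_ids = np.unique(folds)
    if fold_ids.size < 2:
        raise ValueError("grid search requires at least 2 folds")

    best = None
    for point in grid.points():
        rows = []
        for f in fold_ids:
            te = folds == f
            tr = ~te
            if len(set(y[te].tolist())) < 2:
                warnings.warn(f"fold {f} held-out part is single-class; excluded from AUC")
                continue
            model = fit(X[tr], y[tr], grid.model_family, point, seed=seed)
            scores = predict_proba(model, X[te])
            acc, sens, spec = threshold_metrics(scores, y[te])
            rows.append({"fold": int(f), "auc": auc(scores, y[te]),
                         "accuracy": acc, "sensitivity": sens, "specificity": spec})
        if not rows:
            raise UndefinedMetricError("every fold was degenerate")
        mean_auc = float(np.mean([r["auc"] for r in rows]))
        if best is None or mean_auc > best[0] + 1e-12:
            best = (mean_auc, point, pd.DataFrame(rows))
    return best[1], best[2]
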