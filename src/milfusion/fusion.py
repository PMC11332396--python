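"""Joint fusion of the image-derived WSI score with clinical covariates.

The slide classifier's bag-level recurrence probability (the "WSI score")
is appended as one extra column to the clinical feature matrix and an
RF/SVM is trained on the augmented features.  To keep the fused training
matrix leakage-free, the WSI score of every training case is produced
*out-of-fold*: the training cohort is split into k stratified folds, a MIL
model is trained on the other folds (with an inner validation slice for
early stopping) and scores the held-out fold, so no case is ever scored by
a model that saw it.  At test time the score for an unseen case is the
mean over the k fold models (ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import clinical as cl
from .evaluation import auc
from .mil import MILConfig, MILModel, train_mil, predict_wsi_score
from .synthetic import Cohort, PatchBag

__all__ = ["OOFScores", "FusedFeatureMatrix", "FusionModel",
           "compute_oof_wsi_scores", "ensemble_wsi_scores",
           "build_fused_features", "train_fusion", "predict_fusion"]


@dataclass
class OOFScores:
    """Out-of-fold WSI scores with leakage bookkeeping."""

    case_ids: list[str]
    scores: np.ndarray                     # (n,), aligned with case_ids
    fold_of_case: np.ndarray               # (n,), which fold held the case out
    models: list[MILModel]                 # one per fold
    #: scorer_fold[i] is the fold whose model scored case i; leakage-free iff
    #: scorer_fold == fold_of_case everywhere.
    scorer_fold: np.ndarray = None

    def assert_no_leakage(self) -> None:
        if not np.array_equal(self.scorer_fold, self.fold_of_case):
            raise AssertionError("leakage: some case scored by a model that saw it")


@dataclass
class FusedFeatureMatrix:
    case_ids: list[str]
    columns: list[str]                     # clinical columns + "wsi_score"
    matrix: np.ndarray
    provenance: list[str]                  # per-row: "out-of-fold" / "ensemble"


@dataclass
class FusionModel:
    clinical_model: cl.ClinicalModel
    mil_models: list[MILModel]
    feature_set: str
    hyperparameters: dict = field(default_factory=dict)


def _inner_split(idx: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
                 val_fraction: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Stratified inner train/validation split for early stopping."""
    tr, va = [], []
    for cls in np.unique(labels[idx]):
        cls_idx = idx[labels[idx] == cls]
        rng.shuffle(cls_idx)
        n_val = max(1, int(round(val_fraction * cls_idx.size)))
        va.extend(cls_idx[:n_val])
        tr.extend(cls_idx[n_val:])
    return np.array(tr), np.array(va)


def compute_oof_wsi_scores(bags: Sequence[PatchBag], labels: Sequence[int],
                           mil_config: MILConfig, k: int = 10,
                           seed: int = 0) -> OOFScores:
    """Leakage-free per-case WSI scores via stratified k-fold.

    Every case receives exactly one score, predicted by the fold model that
    never saw it; the fold models are kept for test-time ensembling.
    """
    labels = np.asarray(labels).astype(int)
    folds = cl.stratified_folds(labels, k=k, seed=seed)
    rng = np.random.default_rng(seed)
    n = len(bags)
    scores = np.full(n, np.nan)
    scorer = np.full(n, -1)
    models = []
    for f in range(k):
        held = np.flatnonzero(folds == f)
        rest = np.flatnonzero(folds != f)
        tr, va = _inner_split(rest, labels, rng)
        cfg = MILConfig(**{**mil_config.__dict__,
                           "seed": int(rng.integers(0, 2**31 - 1))})
        model, _ = train_mil([bags[i] for i in tr], labels[tr],
                             [bags[i] for i in va], labels[va], cfg)
        for i in held:
            scores[i] = predict_wsi_score(model, bags[i])
            scorer[i] = f
        models.append(model)
    out = OOFScores(case_ids=[b.case_id for b in bags], scores=scores,
                    fold_of_case=folds, models=models, scorer_fold=scorer)
    out.assert_no_leakage()
    return out


def ensemble_wsi_scores(models: Sequence[MILModel], bags: Sequence[PatchBag]) -> np.ndarray:
    """Test-time WSI score: mean bag probability over the fold models."""
    return np.array([np.mean([predict_wsi_score(m, b) for m in models]) for b in bags])


def build_fused_features(clinical_matrix: np.ndarray, columns: Sequence[str],
                         case_ids_clinical: Sequence[str],
                         wsi_scores: np.ndarray, case_ids_wsi: Sequence[str],
                         provenance: str = "out-of-fold") -> FusedFeatureMatrix:
    """Column-wise concatenation of the clinical matrix and the WSI score.

    Case sets must match exactly; a mismatch reports the symmetric
    difference.  Row order follows the clinical matrix.
    """
    set_c, set_w = set(case_ids_clinical), set(case_ids_wsi)
    if set_c != set_w:
        diff = sorted(set_c ^ set_w)
        raise ValueError(f"case mismatch between clinical and WSI scores: {diff}")
    wsi = dict(zip(case_ids_wsi, np.asarray(wsi_scores, dtype=float)))
    col = np.array([wsi[c] for c in case_ids_clinical])
    if np.any((col < 0) | (col > 1)):
        raise ValueError("wsi_score outside [0,1]")
    fused = np.column_stack([np.asarray(clinical_matrix, dtype=float), col])
    return FusedFeatureMatrix(case_ids=list(case_ids_clinical),
                              columns=list(columns) + ["wsi_score"],
                              matrix=fused,
                              provenance=[provenance] * len(case_ids_clinical))


def train_fusion(cohort_train: Cohort, feature_set: str, model_family: str,
                 mil_config: MILConfig, seed: int = 0, k: int = 10,
                 grid: cl.GridSpec | None = None) -> tuple[FusionModel, FusedFeatureMatrix]:
    """Full fused pipeline on the training cohort.

    OOF WSI scores -> fused matrix -> grid-search CV -> final fit on all
    training cases with the winning hyperparameters.
    """
    bags = cohort_train.bags()
    records = cohort_train.records()
    labels = cohort_train.labels()
    oof = compute_oof_wsi_scores(bags, labels, mil_config, k=k, seed=seed)
    Xc = cl.encode_features(records, feature_set)
    fused = build_fused_features(Xc, cl.FEATURE_SETS[feature_set],
                                 [r.case_id for r in records],
                                 oof.scores, oof.case_ids)
    folds = cl.stratified_folds(labels, k=k, seed=seed)
    grid = grid or cl.default_grid(model_family)
    best, _ = cl.grid_search_cv(fused.matrix, labels, grid, folds, seed=seed)
    model = cl.fit(fused.matrix, labels, model_family, best, seed=seed,
                   feature_set=feature_set)
    return (FusionModel(clinical_model=model, mil_models=oof.models,
                        feature_set=feature_set, hyperparameters=best), fused)


def predict_fusion(model: FusionModel, bags: Sequence[PatchBag],
                   records) -> np.ndarray:
    """Fused probabilities for unseen cases (ensemble-mean WSI scores)."""
    Xc = cl.encode_features(records, model.feature_set)
    wsi = ensemble_wsi_scores(model.mil_models, bags)
    fused = build_fused_features(Xc, cl.FEATURE_SETS[model.feature_set],
                                 [r.case_id for r in records],
                                 wsi, [b.case_id for b in bags],
                                 provenance="ensemble")
    return cl.predict_proba(model.clinical_model, fused.matrix)
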