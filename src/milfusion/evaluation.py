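"""Metrics and the cross-validation harness for the slide-level (WSI) arm.

AUC is computed with the Mann-Whitney formulation including the tie
correction, AUC = P(score+ > score-) + 0.5 * P(equal), so it is invariant
under strictly monotone transforms of the scores.  The WSI arm is evaluated
with repeated random 80/10/10 train/validation/test splits (one per fold),
matching how the slide classifier was developed; the clinical arm uses
stratified k-fold (see :mod:`milfusion.clinical`) — the two harnesses are
deliberately distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .mil import MILConfig, train_mil, predict_wsi_score
from .synthetic import PatchBag

__all__ = ["EvalReport", "auc", "threshold_metrics", "split_811",
           "cross_validate_wsi", "summarize"]


class UndefinedMetricError(ValueError):
    """Metric undefined because only one class is present."""


def auc(scores, labels) -> float:
    """Area under the ROC curve via rank statistics (tie-corrected)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: only one class present")
    ranks = rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def threshold_metrics(scores, labels, threshold: float = 0.5) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) at the given probability threshold.

    A case is predicted positive iff its score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise UndefinedMetricError("metrics undefined: only one class present")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return ((tp + tn) / labels.size, tp / (tp + fn), tn / (tn + fp))


@dataclass
class EvalReport:
    """Per-fold and aggregate metrics for one model configuration."""

    model: str
    factors: str
    fold_auc: list[float] = field(default_factory=list)
    fold_accuracy: list[float] = field(default_factory=list)
    fold_sensitivity: list[float] = field(default_factory=list)
    fold_specificity: list[float] = field(default_factory=list)

    def _agg(self, values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        # sample SD (n-1 denominator) across folds
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    @property
    def auc_mean_sd(self) -> tuple[float, float]:
        return self._agg(self.fold_auc)

    @property
    def accuracy_mean_sd(self) -> tuple[float, float]:
        return self._agg(self.fold_accuracy)


def split_811(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random 80/10/10 index split; val and test sizes are round(0.1*n),
    the remainder goes to training."""
    n_val = int(round(0.1 * n))
    n_test = int(round(0.1 * n))
    if n - n_val - n_test < 1 or n_val < 1 or n_test < 1:
        raise ValueError(f"cohort of {n} cases too small for an 80/10/10 split")
    perm = rng.permutation(n)
    return perm[n_val + n_test:], perm[:n_val], perm[n_val:n_val + n_test]


def cross_validate_wsi(bags: Sequence[PatchBag], labels: Sequence[int],
                       mil_config: MILConfig, k: int = 10,
                       seed: int = 0, stratified: bool = False,
                       keep_models: bool = True):
    """k repetitions of a random 80/10/10 split, training the MIL model with
    early stopping on the validation slice and scoring the test slice.

    Returns ``(report, models, fold_details)`` where ``models`` are the k
    fold models (for downstream patch mining with the top-AUC model) and
    ``fold_details`` holds per-fold test indices and scores.
    """
    labels = np.asarray(labels).astype(int)
    n = len(bags)
    rng = np.random.default_rng(seed)
    report = EvalReport(model="attention-MIL", factors="WSI")
    models, fold_details = [], []
    for fold in range(k):
        for attempt in range(100):
            if stratified:
                tr, va, te = _stratified_811(labels, rng)
            else:
                tr, va, te = split_811(n, rng)
            ok = all(len(set(labels[idx].tolist())) == 2 for idx in (tr, va, te))
            if ok:
                break
        else:
            raise ValueError("could not draw a split with both classes in every part")
        cfg = MILConfig(**{**mil_config.__dict__,
                           "seed": int(rng.integers(0, 2**31 - 1))})
        model, _ = train_mil([bags[i] for i in tr], labels[tr],
                             [bags[i] for i in va], labels[va], cfg)
        scores = np.array([predict_wsi_score(model, bags[i]) for i in te])
        report.fold_auc.append(auc(scores, labels[te]))
        acc, sens, spec = threshold_metrics(scores, labels[te])
        report.fold_accuracy.append(acc)
        report.fold_sensitivity.append(sens)
        report.fold_specificity.append(spec)
        if keep_models:
            models.append(model)
        fold_details.append({"test_idx": te, "scores": scores})
    return report, models, fold_details


def _stratified_811(labels: np.ndarray, rng: np.random.Generator):
    tr, va, te = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = idx.size
        n_val = max(1, int(round(0.1 * n)))
        n_test = max(1, int(round(0.1 * n)))
        va.extend(idx[:n_val])
        te.extend(idx[n_val:n_val + n_test])
        tr.extend(idx[n_val + n_test:])
    return np.array(tr), np.array(va), np.array(te)


def summarize(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """One row per (factor set, model family): AUC ± SD and ACC ± SD."""
    rows = []
    for r in reports:
        auc_m, auc_sd = r.auc_mean_sd
        acc_m, acc_sd = r.accuracy_mean_sd
        rows.append({"factors": r.factors, "model": r.model,
                     "auc_mean": auc_m, "auc_sd": auc_sd,
                     "acc_mean": acc_m, "acc_sd": acc_sd})
    return pd.DataFrame(rows, columns=["factors", "model", "auc_mean", "auc_sd",
                                       "acc_mean", "acc_sd"])
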