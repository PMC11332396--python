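"""Interpretation of the trained slide classifier.

Four analyses, all driven by the per-patch attention scores:

* heatmap rendering — normalized attention painted on the tile grid with a
  blue-to-red diverging colormap (high attention = red);
* highly-predictive patch mining — the 10 highest-attention patches from
  each correctly predicted case;
* tumour-area localization — the fraction of highly predictive patches
  whose tile lies inside the annotated tumour mask, reported separately
  for recurrence- and non-recurrence-case patches;
* UMAP embedding (cosine metric) of the mined patch features followed by
  k-means clustering into 10 clusters, flagging clusters dominated by
  recurrence-case patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mil import MILModel, bag_forward, AttentionOutput
from .synthetic import PatchBag, MORPHOLOGY_FLAGS

__all__ = ["HighPatchSet", "ClusterReport", "select_top_patches",
           "extract_highly_predictive", "render_heatmap",
           "tumor_localization_rate", "embed_umap", "cluster_patches"]


@dataclass
class HighPatchSet:
    """Mined high-attention patches across cases.

    ``entries`` has columns (case_id, patch_idx, attention, case_label,
    plus one column per morphology flag when available); sorted by
    attention descending within each case.  ``features`` is the matching
    feature block (row i of features belongs to row i of entries).
    """

    entries: pd.DataFrame
    features: np.ndarray
    provenance: str = ""


@dataclass
class ClusterReport:
    embedding: np.ndarray          # (n, 2)
    cluster_id: np.ndarray         # (n,), 0..k-1
    sizes: np.ndarray              # (k,)
    recurrence_fraction: np.ndarray  # (k,)
    flagged: np.ndarray            # (k,) bool, fraction > 0.5
    inertia: float = 0.0


def select_top_patches(attention: AttentionOutput | np.ndarray, k: int = 10) -> np.ndarray:
    """Indices of the min(k, n) largest normalized attention scores,
    ties broken by lower patch index."""
    scores = attention.normalized_score if isinstance(attention, AttentionOutput) \
        else np.asarray(attention, dtype=float)
    n = scores.shape[0]
    order = np.argsort(-scores, kind="stable")   # stable: ties keep index order
    return order[:min(k, n)]


def extract_highly_predictive(cases: Sequence[tuple[PatchBag, int]],
                              model: MILModel | None = None,
                              predictions: Sequence[float] | None = None,
                              only_correct: bool = True, k: int = 10,
                              threshold: float = 0.5,
                              provenance: str = "") -> HighPatchSet:
    """Top-k attention patches from (by default) correctly predicted cases.

    ``cases`` are (bag, label) pairs.  ``predictions`` may supply
    precomputed WSI scores; otherwise the model computes them.  A case is
    "correct" iff (score >= threshold) == label.
    """
    rows, feats = [], []
    for i, (bag, label) in enumerate(cases):
        out = bag_forward(model, bag) if model is not None else None
        score = float(predictions[i]) if predictions is not None else out.wsi_score
        if only_correct and (score >= threshold) != bool(label):
            continue
        if out is None:
            if model is None:
                raise ValueError("need a model to compute attention scores")
            out = bag_forward(model, bag)
        idx = select_top_patches(out, k=k)
        for j in idx:
            row = {"case_id": bag.case_id, "patch_idx": int(j),
                   "attention": float(out.normalized_score[j]),
                   "case_label": int(label)}
            if bag.morphology_truth is not None:
                for c, name in enumerate(MORPHOLOGY_FLAGS):
                    row[name] = bool(bag.morphology_truth[j, c])
            if bag.signal_truth is not None:
                row["signal"] = bool(bag.signal_truth[j])
            rows.append(row)
            feats.append(bag.features[j])
    entries = pd.DataFrame(rows)
    features = np.asarray(feats, dtype=np.float32) if feats else np.empty((0, 0), np.float32)
    return HighPatchSet(entries=entries, features=features, provenance=provenance)


def _blue_red(scores: np.ndarray) -> np.ndarray:
    """Diverging blue->white->red map; red channel non-decreasing and blue
    channel non-increasing in the score."""
    from matplotlib import colormaps
    return (colormaps["bwr"](np.clip(scores, 0.0, 1.0))[:, :3] * 255).astype(np.uint8)


def render_heatmap(bag: PatchBag, scores: np.ndarray, cell_size: int = 8,
                   background: tuple[int, int, int] = (240, 240, 240)) -> np.ndarray:
    """RGB uint8 image of the attention map on the tile grid.

    Each occupied tile is painted with the colormap of its score; unoccupied
    cells take the background colour.  Image shape is grid extent x
    cell_size per side.
    """
    scores = np.asarray(scores, dtype=float)
    coords = bag.grid_coords
    if len({tuple(c) for c in coords.tolist()}) != coords.shape[0]:
        raise ValueError(f"bag {bag.case_id}: overlapping grid coordinates")
    extent = coords.max(axis=0) + 1
    img = np.empty((extent[0] * cell_size, extent[1] * cell_size, 3), dtype=np.uint8)
    img[:] = np.array(background, dtype=np.uint8)
    colors = _blue_red(scores)
    for (r, c), col in zip(coords, colors):
        img[r * cell_size:(r + 1) * cell_size, c * cell_size:(c + 1) * cell_size] = col
    return img


def tumor_localization_rate(high_patches: HighPatchSet,
                            tumor_masks: dict[str, np.ndarray],
                            coords_of_case: dict[str, np.ndarray]) -> dict[str, float]:
    """Fraction of highly predictive patches whose tile is inside the tumour
    mask, for recurrence-case and non-recurrence-case patches separately.

    ``coords_of_case`` maps case_id to that bag's (n, 2) grid coordinates.
    """
    in_tumor = {0: [], 1: []}
    for _, row in high_patches.entries.iterrows():
        cid = row.case_id
        if cid not in tumor_masks:
            raise ValueError(f"missing tumour mask for case {cid}")
        mask = tumor_masks[cid]
        r, c = coords_of_case[cid][int(row.patch_idx)]
        inside = bool(mask[r, c]) if (r < mask.shape[0] and c < mask.shape[1]) else False
        in_tumor[int(row.case_label)].append(inside)
    return {"recurrence": float(np.mean(in_tumor[1])) if in_tumor[1] else np.nan,
            "non_recurrence": float(np.mean(in_tumor[0])) if in_tumor[0] else np.nan}


def embed_umap(features: np.ndarray, n_neighbors: int = 10, min_dist: float = 0.1,
               metric: str = "cosine", seed: int = 0) -> np.ndarray:
    """2-D UMAP embedding of patch features; deterministic given the seed."""
    import umap

    features = np.asarray(features, dtype=np.float32)
    if features.shape[0] < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} rows, "
                         f"got {features.shape[0]}")
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, metric=metric, random_state=seed)
    return np.asarray(reducer.fit_transform(features), dtype=float)


def cluster_patches(coordinates: np.ndarray, recurrence_flags,
                    k: int = 10, n_init: int = 10, max_iter: int = 30,
                    seed: int = 0) -> ClusterReport:
    """k-means (k-means++ seeding, best of n_init restarts) over the
    embedding coordinates; reports per-cluster size and the fraction of
    patches originating from recurrence cases, flagging clusters where that
    fraction exceeds one half."""
    from sklearn.cluster import KMeans

    coordinates = np.asarray(coordinates, dtype=float)
    flags = np.asarray(recurrence_flags).astype(int)
    if coordinates.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {coordinates.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, random_state=seed)
    ids = km.fit_predict(coordinates)
    sizes = np.bincount(ids, minlength=k)
    frac = np.array([flags[ids == c].mean() if sizes[c] else 0.0 for c in range(k)])
    return ClusterReport(embedding=coordinates, cluster_id=ids, sizes=sizes,
                         recurrence_fraction=frac, flagged=frac > 0.5,
                         inertia=float(km.inertia_))
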