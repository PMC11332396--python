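"""Synthetic cohort generator for the recurrence-prediction pipeline.

Emulates the statistical structure of a cT1-2N0 tongue-SCC cohort: each case
is a bag of patch feature vectors (a stand-in for encoded whole-slide-image
tiles) plus a clinical record with the eight human-assessed covariates.  A
recurrence signal is planted at three levels so every downstream stage has a
known ground truth:

* **feature level** — a fraction of patches in recurrence cases ("signal
  patches") have their mean shifted by ``signal_shift`` along a fixed unit
  direction of feature space;
* **morphology level** — per-patch binary morphology flags (tumour cells,
  inflammatory cells, muscle, adipocytes, salivary gland) are drawn from
  rates conditional on (signal?, case label), so contingency analyses have a
  planted effect;
* **clinical level** — depth of invasion (and with it pT) and the three
  invasion flags are drawn from label-conditional distributions.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; generation is a pure function of the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np

__all__ = [
    "MorphologyRates",
    "LabelEffect",
    "ClinicalEffects",
    "SyntheticConfig",
    "PatchBag",
    "ClinicalRecord",
    "Cohort",
    "generate_cohort",
    "generate_bag",
    "generate_clinical",
    "write_cohort",
    "read_cohort",
    "rasterize_geojson_mask",
    "null_config",
]

MORPHOLOGY_FLAGS = ("tumour", "inflammatory", "muscle", "adipocyte", "salivary")

#: AJCC-8 depth-of-invasion threshold (mm) separating pT1 from pT2 for
#: small primaries; tumour diameter is not simulated.
PT_DOI_THRESHOLD_MM = 5.0

CLINICAL_COLUMNS = (
    "case_id", "pT", "doi_mm", "ly", "v", "pn",
    "age", "sex", "side", "recurrence", "split",
)


class ConfigError(ValueError):
    """A synthetic-cohort configuration field is invalid."""


class ParseError(ValueError):
    """A cohort container on disk is malformed."""


@dataclass(frozen=True)
class MorphologyRates:
    """Per-patch morphology positivity rates for one (signal, label) stratum.

    ``tumour_and_inflammatory`` / ``muscle_and_inflammatory`` are joint
    probabilities; sampling draws the inflammatory flag first and tumour /
    muscle conditionally so the pairwise joints are matched exactly in
    expectation.  Defaults are calibrated to the observed high-attention
    patch proportions in the study cohort (non-recurrence column for the
    background stratum, recurrence column for the signal stratum).
    """

    tumour: float = 0.131
    inflammatory: float = 0.104
    muscle: float = 0.370
    adipocyte: float = 0.535
    salivary: float = 0.014
    tumour_and_inflammatory: float = 0.044
    muscle_and_inflammatory: float = 0.044

    def validate(self, name: str) -> None:
        for f in ("tumour", "inflammatory", "muscle", "adipocyte", "salivary",
                  "tumour_and_inflammatory", "muscle_and_inflammatory"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"morphology_rates[{name}].{f} must be in [0,1], got {v}")
        for joint, single in (("tumour_and_inflammatory", "tumour"),
                              ("muscle_and_inflammatory", "muscle")):
            pj, ps, pi = getattr(self, joint), getattr(self, single), self.inflammatory
            if pj > min(ps, pi) + 1e-12:
                raise ConfigError(
                    f"morphology_rates[{name}].{joint}={pj} exceeds min({single}, inflammatory)")
            if pi < 1.0 and (ps - pj) > (1.0 - pi) + 1e-12:
                raise ConfigError(
                    f"morphology_rates[{name}]: P({single})-P({joint}) exceeds P(not inflammatory)")


#: recurrence-stratum rates, calibrated to the recurrence column of the
#: high-attention patch table (35.0 / 52.3 / 47.7 / 32.3 / 0.5 %, composites
#: 27.3 and 32.3 %).
RECURRENCE_SIGNAL_RATES = MorphologyRates(
    tumour=0.35, inflammatory=0.523, muscle=0.477, adipocyte=0.323,
    salivary=0.005, tumour_and_inflammatory=0.273, muscle_and_inflammatory=0.323,
)


@dataclass(frozen=True)
class LabelEffect:
    """Label-conditional clinical parameters for one outcome class."""

    doi_log_mean: float      # mean of log(doi_mm)
    doi_log_sd: float
    ly_rate: float
    v_rate: float
    pn_rate: float
    age_mean: float = 65.0
    age_sd: float = 12.0
    female_rate: float = 0.35
    right_rate: float = 0.5


@dataclass(frozen=True)
class ClinicalEffects:
    """Clinical covariate distributions for non-recurrence / recurrence cases.

    Defaults plant a higher depth of invasion and higher invasion-flag rates
    in recurrence cases; age, sex and side are label-independent.
    """

    nonrecurrence: LabelEffect = field(
        default_factory=lambda: LabelEffect(
            doi_log_mean=np.log(3.0), doi_log_sd=0.55,
            ly_rate=0.15, v_rate=0.10, pn_rate=0.15))
    recurrence: LabelEffect = field(
        default_factory=lambda: LabelEffect(
            doi_log_mean=np.log(5.5), doi_log_sd=0.45,
            ly_rate=0.45, v_rate=0.30, pn_rate=0.40))

    def for_label(self, label: bool) -> LabelEffect:
        return self.recurrence if label else self.nonrecurrence


def _default_morphology_rates() -> dict:
    background = MorphologyRates()
    return {
        (False, False): background,
        (False, True): background,
        (True, False): background,
        (True, True): RECURRENCE_SIGNAL_RATES,
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of a synthetic cohort.

    ``morphology_rates`` maps ``(signal_patch, recurrence_case)`` strata to
    :class:`MorphologyRates`.  ``signal_shift`` is the mean shift (in feature
    units, i.e. standard deviations of the background Gaussian) applied to
    signal patches along the first feature axis.
    """

    n_cases: int = 148
    recurrence_fraction: float = 34.0 / 148.0
    feature_dim: int = 64
    bag_size_range: tuple[int, int] = (100, 300)
    signal_fraction_recurrence: float = 0.2
    signal_fraction_nonrecurrence: float = 0.0
    signal_shift: float = 6.0
    test_fraction: float = 39.0 / 148.0
    clinical_effects: ClinicalEffects = field(default_factory=ClinicalEffects)
    morphology_rates: dict = field(default_factory=_default_morphology_rates)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ConfigError(f"n_cases must be >= 1, got {self.n_cases}")
        if not 0.0 < self.recurrence_fraction < 1.0:
            raise ConfigError(
                f"recurrence_fraction must be in (0,1), got {self.recurrence_fraction}")
        if self.feature_dim < 2:
            raise ConfigError(f"feature_dim must be >= 2, got {self.feature_dim}")
        lo, hi = self.bag_size_range
        if lo < 1 or hi < lo:
            raise ConfigError(f"bag_size_range must satisfy 1 <= min <= max, got {self.bag_size_range}")
        for f in ("signal_fraction_recurrence", "signal_fraction_nonrecurrence"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{f} must be in [0,1], got {v}")
        if not 0.0 <= self.test_fraction < 1.0:
            raise ConfigError(f"test_fraction must be in [0,1), got {self.test_fraction}")
        for key, rates in self.morphology_rates.items():
            rates.validate(str(key))


def null_config(n_cases: int = 400, seed: int = 0, **overrides) -> SyntheticConfig:
    """A configuration with every label-conditional effect zeroed.

    Signal shift is 0, signal fractions are equal, clinical distributions are
    identical across labels and morphology rates are identical across strata,
    so no model can do better than chance in expectation.
    """
    flat = ClinicalEffects(nonrecurrence=ClinicalEffects().nonrecurrence,
                           recurrence=ClinicalEffects().nonrecurrence)
    background = MorphologyRates()
    rates = {k: background for k in [(False, False), (False, True), (True, False), (True, True)]}
    return SyntheticConfig(
        n_cases=n_cases, signal_shift=0.0,
        signal_fraction_recurrence=0.1, signal_fraction_nonrecurrence=0.1,
        clinical_effects=flat, morphology_rates=rates, seed=seed, **overrides)


@dataclass
class PatchBag:
    """One case's bag of patch feature vectors on a non-overlapping tile grid."""

    case_id: str
    features: np.ndarray                 # (n_patches, feature_dim) float32
    grid_coords: np.ndarray              # (n_patches, 2) int32 (row, col)
    morphology_truth: np.ndarray | None = None   # (n_patches, 5) bool
    signal_truth: np.ndarray | None = None       # (n_patches,) bool
    magnification_tag: str = "20x"

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    def validate(self) -> None:
        n = self.n_patches
        if n < 1:
            raise ValueError(f"bag {self.case_id}: empty bag")
        if self.grid_coords.shape != (n, 2):
            raise ValueError(f"bag {self.case_id}: coords shape mismatch")
        if len({tuple(c) for c in self.grid_coords.tolist()}) != n:
            raise ValueError(f"bag {self.case_id}: duplicate grid coordinates")
        for name, arr in (("morphology_truth", self.morphology_truth),
                          ("signal_truth", self.signal_truth)):
            if arr is not None and arr.shape[0] != n:
                raise ValueError(f"bag {self.case_id}: {name} length mismatch")


@dataclass
class ClinicalRecord:
    """Eight human-assessed covariates plus the recurrence outcome."""

    case_id: str
    pT: int                  # 1 or 2
    doi_mm: float            # depth of invasion, millimetres
    lymphatic_invasion: bool
    vascular_invasion: bool
    perineural_invasion: bool
    age: float
    sex: str                 # "M" / "F"
    side: str                # "left" / "right"
    recurrence: bool


@dataclass
class Cohort:
    """Paired bags and clinical records with a train/test split tag per case."""

    cases: list[tuple[PatchBag, ClinicalRecord]]
    split_tag: dict[str, str]                    # case_id -> "train" / "test"
    tumor_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [bag.case_id for bag, _ in self.cases]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate case_id(s): {dup}")
        for bag, rec in self.cases:
            if bag.case_id != rec.case_id:
                raise ValueError(f"bag/record case_id mismatch: {bag.case_id} vs {rec.case_id}")

    def subset(self, tag: str) -> "Cohort":
        sel = [(b, r) for b, r in self.cases if self.split_tag[b.case_id] == tag]
        return Cohort(
            cases=sel,
            split_tag={b.case_id: tag for b, _ in sel},
            tumor_masks={b.case_id: self.tumor_masks[b.case_id]
                         for b, _ in sel if b.case_id in self.tumor_masks})

    def bags(self) -> list[PatchBag]:
        return [b for b, _ in self.cases]

    def records(self) -> list[ClinicalRecord]:
        return [r for _, r in self.cases]

    def labels(self) -> np.ndarray:
        return np.array([int(r.recurrence) for _, r in self.cases])


def _sample_morphology(rates: MorphologyRates, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw (n, 5) morphology flags matching marginals and the two pairwise joints."""
    infl = rng.random(n) < rates.inflammatory
    flags = np.zeros((n, 5), dtype=bool)
    flags[:, 1] = infl

    def conditional(p_marg: float, p_joint: float) -> np.ndarray:
        pi = rates.inflammatory
        p_given_i = p_joint / pi if pi > 0 else 0.0
        p_given_not = (p_marg - p_joint) / (1 - pi) if pi < 1 else 0.0
        p = np.where(infl, p_given_i, p_given_not)
        return rng.random(n) < p

    flags[:, 0] = conditional(rates.tumour, rates.tumour_and_inflammatory)
    flags[:, 2] = conditional(rates.muscle, rates.muscle_and_inflammatory)
    flags[:, 3] = rng.random(n) < rates.adipocyte
    flags[:, 4] = rng.random(n) < rates.salivary
    return flags


def generate_bag(label: bool, config: SyntheticConfig, rng: np.random.Generator,
                 case_id: str = "case") -> PatchBag:
    """Generate one bag: background patches are spherical standard Gaussians,
    signal patches are shifted by ``signal_shift`` along the first feature axis.
    """
    lo, hi = config.bag_size_range
    n = int(rng.integers(lo, hi + 1))
    d = config.feature_dim
    frac = (config.signal_fraction_recurrence if label
            else config.signal_fraction_nonrecurrence)
    signal = rng.random(n) < frac
    feats = rng.standard_normal((n, d))
    feats[signal, 0] += config.signal_shift
    # lay patches on a square-ish grid with ~30% spare cells, unique tiles
    side = int(np.ceil(np.sqrt(n * 1.3)))
    cells = rng.choice(side * side, size=n, replace=False)
    coords = np.stack([cells // side, cells % side], axis=1).astype(np.int32)
    morph = np.zeros((n, 5), dtype=bool)
    for is_signal in (False, True):
        m = signal == is_signal
        if m.any():
            rates = config.morphology_rates[(is_signal, bool(label))]
            morph[m] = _sample_morphology(rates, int(m.sum()), rng)
    return PatchBag(case_id=case_id, features=feats.astype(np.float32),
                    grid_coords=coords, morphology_truth=morph,
                    signal_truth=signal)


def generate_clinical(label: bool, config: SyntheticConfig, rng: np.random.Generator,
                      case_id: str = "case") -> ClinicalRecord:
    """Draw one clinical record from the label-conditional distributions.

    doi_mm is log-normal, clipped to (0.1, 10] mm so that AJCC-8 pT from DOI
    stays in {1, 2}; pT is deterministic from doi_mm via the 5 mm threshold.
    """
    eff = config.clinical_effects.for_label(label)
    doi = float(np.clip(np.exp(rng.normal(eff.doi_log_mean, eff.doi_log_sd)), 0.1, 10.0))
    pt = 1 if doi <= PT_DOI_THRESHOLD_MM else 2
    age = float(np.clip(rng.normal(eff.age_mean, eff.age_sd), 20.0, 95.0))
    return ClinicalRecord(
        case_id=case_id, pT=pt, doi_mm=doi,
        lymphatic_invasion=bool(rng.random() < eff.ly_rate),
        vascular_invasion=bool(rng.random() < eff.v_rate),
        perineural_invasion=bool(rng.random() < eff.pn_rate),
        age=age,
        sex="F" if rng.random() < eff.female_rate else "M",
        side="right" if rng.random() < eff.right_rate else "left",
        recurrence=bool(label))


def _tumor_mask(bag: PatchBag) -> np.ndarray:
    """Boolean tile grid: True where the patch is signal- or tumour-flagged."""
    extent = bag.grid_coords.max(axis=0) + 1
    mask = np.zeros(tuple(extent), dtype=bool)
    flagged = bag.signal_truth.copy() if bag.signal_truth is not None else np.zeros(bag.n_patches, bool)
    if bag.morphology_truth is not None:
        flagged |= bag.morphology_truth[:, 0]     # tumour-cell flag
    for (r, c), f in zip(bag.grid_coords, flagged):
        if f:
            mask[r, c] = True
    return mask


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a full cohort: exactly ``round(n_cases*recurrence_fraction)``
    recurrence cases, stratified train/test tags, per-case tumour masks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_rec = int(round(config.n_cases * config.recurrence_fraction))
    labels = np.array([True] * n_rec + [False] * (config.n_cases - n_rec))
    rng.shuffle(labels)

    cases = []
    masks = {}
    for i, label in enumerate(labels):
        cid = f"case_{i:04d}"
        bag = generate_bag(bool(label), config, rng, case_id=cid)
        rec = generate_clinical(bool(label), config, rng, case_id=cid)
        cases.append((bag, rec))
        masks[cid] = _tumor_mask(bag)

    # stratified train/test tags
    split = {}
    for label in (False, True):
        ids = [b.case_id for b, r in cases if r.recurrence == label]
        n_test = int(round(len(ids) * config.test_fraction))
        test_ids = set(rng.choice(ids, size=n_test, replace=False)) if n_test else set()
        for cid in ids:
            split[cid] = "test" if cid in test_ids else "train"
    return Cohort(cases=cases, split_tag=split, tumor_masks=masks)


# ---------------------------------------------------------------------------
# container I/O: clinical CSV + per-case HDF5 groups

def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to ``path`` (a directory): ``clinical.csv`` + ``bags.h5``.

    The HDF5 file holds one group per case with datasets ``features``
    (float32, n×d), ``coords`` (int32, n×2), and optionally ``morphology``
    (uint8, n×5), ``signal`` (uint8, n) and ``tumor_mask`` (uint8 grid).
    """
    import pandas as pd
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for bag, r in cohort.cases:
        rows.append({
            "case_id": r.case_id, "pT": r.pT, "doi_mm": r.doi_mm,
            "ly": int(r.lymphatic_invasion), "v": int(r.vascular_invasion),
            "pn": int(r.perineural_invasion), "age": r.age, "sex": r.sex,
            "side": r.side, "recurrence": int(r.recurrence),
            "split": cohort.split_tag[r.case_id]})
    pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS)).to_csv(
        path / "clinical.csv", index=False, float_format="%.17g")

    with h5py.File(path / "bags.h5", "w") as f:
        for bag, _ in cohort.cases:
            g = f.create_group(bag.case_id)
            g.create_dataset("features", data=bag.features.astype(np.float32))
            g.create_dataset("coords", data=bag.grid_coords.astype(np.int32))
            if bag.morphology_truth is not None:
                g.create_dataset("morphology", data=bag.morphology_truth.astype(np.uint8))
            if bag.signal_truth is not None:
                g.create_dataset("signal", data=bag.signal_truth.astype(np.uint8))
            if bag.case_id in cohort.tumor_masks:
                g.create_dataset("tumor_mask",
                                 data=cohort.tumor_masks[bag.case_id].astype(np.uint8))
            g.attrs["magnification_tag"] = bag.magnification_tag


def read_cohort(path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`; round trip is lossless."""
    import pandas as pd
    from pathlib import Path

    path = Path(path)
    df = pd.read_csv(path / "clinical.csv", float_precision="round_trip")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"clinical.csv missing required column(s): {missing}")
    dup = df.case_id[df.case_id.duplicated()].tolist()
    if dup:
        raise ParseError(f"duplicate case_id(s) in clinical.csv: {sorted(set(dup))}")

    records = {}
    split = {}
    for _, row in df.iterrows():
        cid = str(row.case_id)
        records[cid] = ClinicalRecord(
            case_id=cid, pT=int(row.pT), doi_mm=float(row.doi_mm),
            lymphatic_invasion=bool(row.ly), vascular_invasion=bool(row.v),
            perineural_invasion=bool(row.pn), age=float(row.age),
            sex=str(row.sex), side=str(row.side), recurrence=bool(row.recurrence))
        split[cid] = str(row.split)

    cases = []
    masks = {}
    with h5py.File(path / "bags.h5", "r") as f:
        for cid in df.case_id.astype(str):
            if cid not in f:
                raise ParseError(f"bags.h5 missing group for case_id {cid!r}")
            g = f[cid]
            if "features" not in g or "coords" not in g:
                raise ParseError(f"bags.h5 group {cid!r} missing features/coords")
            bag = PatchBag(
                case_id=cid,
                features=np.asarray(g["features"], dtype=np.float32),
                grid_coords=np.asarray(g["coords"], dtype=np.int32),
                morphology_truth=(np.asarray(g["morphology"]).astype(bool)
                                  if "morphology" in g else None),
                signal_truth=(np.asarray(g["signal"]).astype(bool)
                              if "signal" in g else None),
                magnification_tag=str(g.attrs.get("magnification_tag", "20x")))
            bag.validate()
            cases.append((bag, records[cid]))
            if "tumor_mask" in g:
                masks[cid] = np.asarray(g["tumor_mask"]).astype(bool)
    return Cohort(cases=cases, split_tag=split, tumor_masks=masks)


def rasterize_geojson_mask(geojson: dict | str, grid_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize GeoJSON polygons in tile-grid coordinates to a boolean grid.

    A tile (row, col) is inside iff its centre (col+0.5, row+0.5) falls in a
    polygon (x = column, y = row, as in QuPath exports rescaled to tiles).
    """
    from shapely.geometry import shape, Point

    if isinstance(geojson, str):
        geojson = json.loads(geojson)
    feats = geojson.get("features", [geojson]) if geojson.get("type") != "Feature" else [geojson]
    polys = [shape(f["geometry"] if "geometry" in f else f) for f in feats]
    mask = np.zeros(grid_shape, dtype=bool)
    for r in range(grid_shape[0]):
        for c in range(grid_shape[1]):
            p = Point(c + 0.5, r + 0.5)
            if any(poly.contains(p) for poly in polys):
                mask[r, c] = True
    return mask
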