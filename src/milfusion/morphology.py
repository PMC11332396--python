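"""Contingency-table analysis of patch morphology by recurrence group.

Each highly predictive patch carries binary flags for five morphologies
(tumour cells, inflammatory cells, muscle, adipocytes, salivary gland) and
a group from its case of origin (recurrence / non-recurrence).  Every flag,
plus the two composites tumour∧inflammatory and muscle∧inflammatory, is
cross-tabulated against group and tested with a two-sided Fisher's exact
test using the point-probability convention (the two-sided p-value is the
sum of hypergeometric probabilities of all tables with the observed margins
whose point probability does not exceed the observed table's — the
convention of R's ``fisher.test``).  Cohort-characteristics comparisons of
continuous variables use Welch's unequal-variance t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = ["FEATURES", "PRIMITIVE_FLAGS", "ContingencyTable", "FeatureStatsRow",
           "annotations_from_high_patches", "annotations_from_counts",
           "build_contingency",
           "fisher_exact_two_sided", "percent_positive", "feature_table",
           "welch_t_test", "format_p"]

PRIMITIVE_FLAGS = ("tumour", "inflammatory", "muscle", "adipocyte", "salivary")

#: report order: five primitives then the two composite features
FEATURES = PRIMITIVE_FLAGS + ("tumour_and_inflammatory", "muscle_and_inflammatory")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of one binary feature across the two patch groups.

    a, b: non-recurrence negative / positive; c, d: recurrence negative /
    positive.
    """

    feature: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_nonrecurrence(self) -> int:
        return self.a + self.b

    @property
    def n_recurrence(self) -> int:
        return self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class FeatureStatsRow:
    feature: str
    neg_nonrecurrence: int
    pos_nonrecurrence: int
    neg_recurrence: int
    pos_recurrence: int
    pct_pos_nonrecurrence: float
    pct_pos_recurrence: float
    p_value: float
    p_formatted: str


def annotations_from_high_patches(entries: pd.DataFrame) -> pd.DataFrame:
    """Per-patch annotation table (group + flags + composites) from mined
    high-attention patch entries carrying morphology truth."""
    df = pd.DataFrame({
        "group": np.where(entries["case_label"].astype(int) == 1,
                          "recurrence", "non-recurrence")})
    for flag in PRIMITIVE_FLAGS:
        df[flag] = entries[flag].astype(bool).to_numpy()
    return add_composites(df)


def add_composites(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["tumour_and_inflammatory"] = df["tumour"] & df["inflammatory"]
    df["muscle_and_inflammatory"] = df["muscle"] & df["inflammatory"]
    return df


def build_contingency(annotations: pd.DataFrame, feature: str) -> ContingencyTable:
    """Cross-tabulate group x flag for one feature.

    ``feature`` may be any boolean column of ``annotations`` (e.g. automated
    nuclear-detection flags such as ``tumour_detected``), not only the seven
    standard morphology features.
    """
    if feature not in annotations.columns:
        if feature not in FEATURES:
            raise ValueError(f"unknown feature: {feature!r}")
        annotations = add_composites(annotations)
    groups = set(annotations["group"])
    if not {"recurrence", "non-recurrence"} <= groups:
        raise ValueError(f"annotations must contain both groups, found {sorted(groups)}")
    flag = annotations[feature].astype(bool)
    non = annotations["group"] == "non-recurrence"
    rec = annotations["group"] == "recurrence"
    return ContingencyTable(
        feature=feature,
        a=int((non & ~flag).sum()), b=int((non & flag).sum()),
        c=int((rec & ~flag).sum()), d=int((rec & flag).sum()))


def fisher_exact_two_sided(table: ContingencyTable | np.ndarray,
                           rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher's exact p-value (point-probability criterion).

    Sums the hypergeometric probabilities, over all tables sharing the
    observed margins, of those whose point probability does not exceed the
    observed table's (within relative tolerance ``rel_tol`` — the convention
    of R's ``fisher.test``).  Implemented directly on the vectorized
    log-pmf so that large batch comparisons stay cheap; agreement with
    ``scipy.stats.fisher_exact`` is asserted in the test suite.

    A zero margin makes every table with those margins identical; by
    convention p = 1 with a warning.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable) else np.asarray(table)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("expected a nonnegative 2x2 table")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, b + d):
        warnings.warn("zero margin in contingency table; p = 1 by convention")
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    x = np.arange(lo, hi + 1)
    logpmf = (_logcomb(r1, x) + _logcomb(r2, c1 - x) - _logcomb(n, c1))
    logpmf -= logpmf.max()          # stabilize before exponentiating
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    p_obs = pmf[a - lo]
    mask = pmf <= p_obs * (1.0 + rel_tol)
    if mask.all():
        return 1.0
    return float(min(pmf[mask].sum(), 1.0))


def _logcomb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def percent_positive(table: ContingencyTable, group: str) -> float:
    """Percentage of positive patches in one group, half-up to one decimal."""
    if group == "non-recurrence":
        pos, total = table.b, table.n_nonrecurrence
    elif group == "recurrence":
        pos, total = table.d, table.n_recurrence
    else:
        raise ValueError(f"unknown group: {group!r}")
    if total == 0:
        raise ValueError(f"group {group!r} has zero total")
    return float(Decimal(100.0 * pos / total).quantize(Decimal("0.1"),
                                                       rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    """p-values below 0.001 print as "<0.001", otherwise to 3 decimals."""
    if p < 0.001:
        return "<0.001"
    return str(Decimal(p).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def feature_table(annotations: pd.DataFrame) -> list[FeatureStatsRow]:
    """One row per feature (five primitives + two composites) with counts,
    percentages and the two-sided Fisher p-value."""
    if annotations.empty:
        raise ValueError("no annotations")
    annotations = add_composites(annotations) \
        if "tumour_and_inflammatory" not in annotations.columns else annotations
    rows = []
    for feature in FEATURES:
        t = build_contingency(annotations, feature)
        p = fisher_exact_two_sided(t)
        rows.append(FeatureStatsRow(
            feature=feature,
            neg_nonrecurrence=t.a, pos_nonrecurrence=t.b,
            neg_recurrence=t.c, pos_recurrence=t.d,
            pct_pos_nonrecurrence=percent_positive(t, "non-recurrence"),
            pct_pos_recurrence=percent_positive(t, "recurrence"),
            p_value=p, p_formatted=format_p(p)))
    return rows


def feature_table_frame(rows: list[FeatureStatsRow]) -> pd.DataFrame:
    """The feature table as a printable DataFrame."""
    return pd.DataFrame([{
        "feature": r.feature,
        "non_recurrence": f"{r.pos_nonrecurrence} ({r.pct_pos_nonrecurrence})",
        "recurrence": f"{r.pos_recurrence} ({r.pct_pos_recurrence})",
        "p": r.p_formatted,
    } for r in rows])


def annotations_from_counts(n_nonrecurrence: int, n_recurrence: int,
                            positives: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Reconstruct a patch-level annotation table from summary counts.

    ``positives`` maps each of the five primitive flags and the two
    composites to (positive count in non-recurrence, positive count in
    recurrence).  The construction matches every primitive marginal and
    both pairwise joints exactly (overlaps beyond those are arbitrary),
    so downstream contingency tables reproduce the counts verbatim.
    """
    frames = []
    for group, n, col in (("non-recurrence", n_nonrecurrence, 0),
                          ("recurrence", n_recurrence, 1)):
        nI = positives["inflammatory"][col]
        nT = positives["tumour"][col]
        nM = positives["muscle"][col]
        nTI = positives["tumour_and_inflammatory"][col]
        nMI = positives["muscle_and_inflammatory"][col]
        nA = positives["adipocyte"][col]
        nS = positives["salivary"][col]
        if nTI > min(nT, nI) or nMI > min(nM, nI):
            raise ValueError(f"{group}: composite count exceeds a primitive count")
        if nI + (nT - nTI) + (nM - nMI) > n:
            raise ValueError(f"{group}: counts do not fit in {n} patches")
        flags = np.zeros((n, 5), dtype=bool)
        flags[:nI, 1] = True                                   # inflammatory
        flags[:nTI, 0] = True                                  # tumour inside I
        flags[nI:nI + nT - nTI, 0] = True                      # tumour outside I
        flags[nI - nMI:nI, 2] = True                           # muscle inside I
        start = nI + nT - nTI
        flags[start:start + nM - nMI, 2] = True                # muscle outside I
        flags[:nA, 3] = True
        flags[:nS, 4] = True
        df = pd.DataFrame(flags, columns=list(PRIMITIVE_FLAGS))
        df.insert(0, "group", group)
        frames.append(df)
    return add_composites(pd.concat(frames, ignore_index=True))


def welch_t_test(values_a, values_b) -> tuple[float, float]:
    """Welch's unequal-variance t statistic with Satterthwaite df and the
    two-sided p-value.  Identical constant samples return (0.0, 1.0)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("samples must be finite")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)
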