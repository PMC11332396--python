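"""Contingency tables, Fisher's exact test (with enumeration oracle), t-tests."""

import math

import numpy as np
import pandas as pd
import pytest

from milfusion.morphology import (
    ContingencyTable, annotations_from_counts, annotations_from_high_patches,
    build_contingency, feature_table, fisher_exact_two_sided, format_p,
    percent_positive, welch_t_test,
)

# manual morphology counts of the 990 high-attention training patches
# (770 non-recurrence / 220 recurrence): (positives non-rec, positives rec)
TRAIN_PATCH_POSITIVES = {
    "tumour": (101, 77),
    "inflammatory": (80, 115),
    "muscle": (285, 105),
    "adipocyte": (412, 71),
    "salivary": (11, 1),
    "tumour_and_inflammatory": (34, 60),
    "muscle_and_inflammatory": (34, 71),
}


def fisher_oracle(a, b, c, d, tol=1e-7):
    """Brute-force two-sided Fisher p: enumerate every table with the observed
    margins and sum hypergeometric point probabilities <= the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):  # P(first cell = x) under the hypergeometric null
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = pmf(a)
    return sum(p for x in range(lo, hi + 1)
               if (p := pmf(x)) <= p_obs * (1 + tol))


class TestBuildContingency:
    def test_reconstructed_tumour_row(self):
        ann = annotations_from_counts(770, 220, TRAIN_PATCH_POSITIVES)
        t = build_contingency(ann, "tumour")
        assert (t.a, t.b, t.c, t.d) == (669, 101, 143, 77)
        assert (t.n_nonrecurrence, t.n_recurrence) == (770, 220)

    def test_all_negative_flag(self):
        ann = pd.DataFrame({"group": ["recurrence", "non-recurrence"] * 5,
                            "tumour": False, "inflammatory": False,
                            "muscle": False, "adipocyte": False, "salivary": False})
        t = build_contingency(ann, "tumour")
        assert t.b == 0 and t.d == 0

    def test_counts_sum_to_total(self):
        ann = annotations_from_counts(50, 30, {k: (5, 3) for k in TRAIN_PATCH_POSITIVES})
        t = build_contingency(ann, "muscle")
        assert t.a + t.b + t.c + t.d == 80

    def test_single_group_rejected(self):
        ann = pd.DataFrame({"group": ["recurrence"] * 4, "tumour": True,
                            "inflammatory": False, "muscle": False,
                            "adipocyte": False, "salivary": False})
        with pytest.raises(ValueError, match="both groups"):
            build_contingency(ann, "tumour")

    def test_unknown_feature_rejected(self):
        ann = annotations_from_counts(10, 10, {k: (1, 1) for k in TRAIN_PATCH_POSITIVES})
        with pytest.raises(ValueError, match="unknown feature"):
            build_contingency(ann, "stroma")


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided(np.array([[10, 10], [10, 10]])) == 1.0

    def test_extreme_5x5_table(self):
        # margins 5/5 vs 5/5, observed (0,5;5,0): only the two extreme tables
        # out of C(10,5)=252 arrangements are as unlikely -> p = 2/252
        p = fisher_exact_two_sided(np.array([[0, 5], [5, 0]]))
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_zero_margin_convention(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_two_sided(np.array([[0, 0], [3, 4]])) == 1.0

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 40, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            t = ContingencyTable("f", int(a), int(b), int(c), int(d))
            assert fisher_exact_two_sided(t) == pytest.approx(
                fisher_oracle(a, b, c, d), rel=1e-7)

    def test_matches_scipy_on_random_tables(self):
        from scipy.stats import fisher_exact as scipy_fisher
        rng = np.random.default_rng(2)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 60, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            ours = fisher_exact_two_sided(np.array([[a, b], [c, d]]))
            ref = scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(min(ref, 1.0), rel=1e-7)

    def test_invariance_under_group_and_label_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 30, size=4))
            p = fisher_exact_two_sided(np.array([[a, b], [c, d]]))
            p_group = fisher_exact_two_sided(np.array([[c, d], [a, b]]))
            p_both = fisher_exact_two_sided(np.array([[d, c], [b, a]]))
            assert p == pytest.approx(p_group, rel=1e-9)
            assert p == pytest.approx(p_both, rel=1e-9)


class TestFormatting:
    @pytest.mark.parametrize("pos,total,expected", [
        (77, 220, 35.0), (115, 220, 52.3), (0, 50, 0.0), (101, 770, 13.1),
    ])
    def test_percent_half_up_one_decimal(self, pos, total, expected):
        t = ContingencyTable("f", total - pos, pos, 1, 1)
        assert percent_positive(t, "non-recurrence") == expected

    def test_zero_total_rejected(self):
        t = ContingencyTable("f", 0, 0, 1, 1)
        with pytest.raises(ValueError, match="zero total"):
            percent_positive(t, "non-recurrence")

    @pytest.mark.parametrize("p,expected", [
        (0.0005, "<0.001"), (0.004819, "0.005"), (0.48192, "0.482"), (1.0, "1.000"),
    ])
    def test_p_value_formatting(self, p, expected):
        assert format_p(p) == expected


class TestFeatureTable:
    def test_reproduces_reference_percentages_and_p_bins(self):
        ann = annotations_from_counts(770, 220, TRAIN_PATCH_POSITIVES)
        rows = {r.feature: r for r in feature_table(ann)}
        assert rows["tumour"].pct_pos_nonrecurrence == 13.1
        assert rows["tumour"].pct_pos_recurrence == 35.0
        assert rows["inflammatory"].pct_pos_recurrence == 52.3
        assert rows["adipocyte"].pct_pos_nonrecurrence == 53.5
        assert rows["tumour_and_inflammatory"].pct_pos_recurrence == 27.3
        for f in ("tumour", "inflammatory", "adipocyte",
                  "tumour_and_inflammatory", "muscle_and_inflammatory"):
            assert rows[f].p_formatted == "<0.001"
        assert rows["muscle"].p_formatted == "0.005"
        assert rows["salivary"].p_formatted == "0.482"

    def test_row_order_and_composite_consistency(self):
        ann = annotations_from_counts(100, 60, {
            "tumour": (20, 30), "inflammatory": (15, 25), "muscle": (30, 20),
            "adipocyte": (40, 10), "salivary": (2, 1),
            "tumour_and_inflammatory": (5, 12), "muscle_and_inflammatory": (8, 10)})
        rows = feature_table(ann)
        assert [r.feature for r in rows] == [
            "tumour", "inflammatory", "muscle", "adipocyte", "salivary",
            "tumour_and_inflammatory", "muscle_and_inflammatory"]
        by = {r.feature: r for r in rows}
        for joint, single in (("tumour_and_inflammatory", "tumour"),
                              ("muscle_and_inflammatory", "muscle")):
            assert by[joint].pos_nonrecurrence <= min(
                by[single].pos_nonrecurrence, by["inflammatory"].pos_nonrecurrence)
        for r in rows:
            total_pct = (percent_positive(build_contingency(ann, r.feature), "recurrence"))
            assert 0.0 <= total_pct <= 100.0

    def test_sampling_at_reference_rates_converges(self):
        # binomial tolerance at ~990 patches: sampled percentages within 2 pts
        rng = np.random.default_rng(4)
        n_non, n_rec = 770, 220
        ann = pd.DataFrame({
            "group": ["non-recurrence"] * n_non + ["recurrence"] * n_rec,
            "tumour": np.r_[rng.random(n_non) < 0.131, rng.random(n_rec) < 0.35],
            "inflammatory": np.r_[rng.random(n_non) < 0.104, rng.random(n_rec) < 0.523],
            "muscle": False, "adipocyte": False, "salivary": False})
        rows = {r.feature: r for r in feature_table(ann)}
        assert rows["tumour"].pct_pos_recurrence == pytest.approx(35.0, abs=2 * 3.2)
        assert rows["inflammatory"].pct_pos_recurrence == pytest.approx(52.3, abs=2 * 3.4)

    def test_from_high_patch_entries(self):
        entries = pd.DataFrame({
            "case_label": [1, 1, 0, 0],
            "tumour": [True, False, False, True],
            "inflammatory": [True, True, False, False],
            "muscle": [False] * 4, "adipocyte": [False] * 4, "salivary": [False] * 4})
        ann = annotations_from_high_patches(entries)
        assert list(ann["group"]) == ["recurrence", "recurrence",
                                      "non-recurrence", "non-recurrence"]
        assert ann["tumour_and_inflammatory"].tolist() == [True, False, False, False]


class TestWelchT:
    def test_identical_samples(self):
        assert welch_t_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_large_shift_is_significant(self):
        stat, p = welch_t_test([1, 2, 3], [11, 12, 13])
        assert p < 0.01

    def test_swap_negates_statistic(self):
        a, b = [1.0, 2.5, 3.1, 4.0], [2.0, 2.2, 5.1, 6.3]
        sa, pa = welch_t_test(a, b)
        sb, pb = welch_t_test(b, a)
        assert sa == pytest.approx(-sb)
        assert pa == pytest.approx(pb)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_t_test([1.0], [1, 2, 3])
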