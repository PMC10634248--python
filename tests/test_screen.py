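"""Kruskal-Wallis screening, BH adjustment, two-group tests, prevalence, WMH."""

import itertools

import numpy as np
import pytest
from scipy import stats

from immunoprofiles.screen import (
    bh_adjust,
    kruskal_wallis,
    prevalence_summary,
    screen_markers,
    two_group_compare,
    wmh_compare,
)
from immunoprofiles.synth import (
    DISCRIMINATING_MARKERS,
    generate_nci_substudy,
    generate_wmh_annotations,
)
from tests.conftest import make_annotations, make_table


def kw_h_oracle(values, groups):
    """Independent H computation: rank formula with midranks and tie factor."""
    values = np.asarray(values, float)
    ranks = stats.rankdata(values)
    n = len(values)
    h = 0.0
    for g in set(groups):
        r = ranks[np.asarray(groups) == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1 - ((counts**3 - counts).sum()) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_two_balanced_groups_hand_value(self):
        h, _ = kruskal_wallis([1, 2, 3, 4, 5, 6], list("AAABBB"))
        assert h == pytest.approx(3.857, abs=5e-4)

    def test_three_singleton_groups(self):
        h, _ = kruskal_wallis([5.0, 1.0, 9.0], ["a", "b", "c"])
        assert h == pytest.approx(2.0)

    def test_identical_groups_define_zero(self):
        h, p = kruskal_wallis([3.0] * 6, list("AAABBB"))
        assert (h, p) == (0.0, 1.0)

    def test_matches_rank_formula_and_permutation_oracle_small_n(self):
        """H agrees with an independent rank-formula oracle, and the exact
        permutation p computed from our H agrees with one computed from the
        oracle's H, on random instances with N <= 8 (ties included).

        Exchanging labels within a group leaves H unchanged, so the exact
        null enumerates group memberships (combinations), not raw
        permutations.
        """
        rng = np.random.default_rng(42)
        for _ in range(12):
            n = int(rng.integers(5, 9))
            values = rng.integers(0, 5, size=n).astype(float)  # forces ties
            if np.all(values == values[0]):
                continue
            n_a = n // 2
            groups = np.array(["A"] * n_a + ["B"] * (n - n_a))
            h_ours, _ = kruskal_wallis(values, groups)
            h_oracle = kw_h_oracle(values, groups)
            assert h_ours == pytest.approx(h_oracle, abs=1e-9)

            def perm_p(stat_fn, h_obs):
                count = total = 0
                for comb in itertools.combinations(range(n), n_a):
                    g = np.array(["B"] * n)
                    g[list(comb)] = "A"
                    count += stat_fn(values, g) >= h_obs - 1e-12
                    total += 1
                return count / total

            p_ours = perm_p(lambda v, g: kruskal_wallis(v, g)[0], h_ours)
            p_oracle = perm_p(kw_h_oracle, h_oracle)
            assert abs(p_ours - p_oracle) <= 0.02

    def test_exact_permutation_p_for_the_hand_example(self):
        values = np.array([1.0, 2, 3, 4, 5, 6])
        groups = np.array(list("AAABBB"))
        h_obs, _ = kruskal_wallis(values, groups)
        count = total = 0
        for comb in itertools.combinations(range(6), 3):
            g = np.array(["B"] * 6)
            g[list(comb)] = "A"
            h, _ = kruskal_wallis(values, g)
            count += h >= h_obs - 1e-12
            total += 1
        assert count / total == pytest.approx(0.100, abs=1e-9)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.005, 0.1, 0.2), (0.015, 0.15, 0.2)),
            ((0.3, 0.3, 0.3), (0.3, 0.3, 0.3)),
            ((0.7,), (0.7,)),
        ],
    )
    def test_hand_computed_step_up_values(self, pvals, expected):
        np.testing.assert_allclose(bh_adjust(pvals), expected, atol=1e-12)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(50)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_ref, atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone_when_sorted(self):
        rng = np.random.default_rng(2)
        p = np.sort(rng.random(30))
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all((q >= 0) & (q <= 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestTwoGroupCompare:
    def test_normal_shifted_groups_use_student_t(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)])
        flags = np.repeat([False, True], 30)
        res = two_group_compare(x, flags)
        assert res.test_name == "t"
        assert res.p < 0.01
        # agrees with the reference pooled t-test
        ref = stats.ttest_ind(x[:30], x[30:], equal_var=True)
        assert res.p == pytest.approx(ref.pvalue)

    def test_identical_groups_not_significant(self):
        x = np.tile([1.0, 2, 3, 4, 5], 2)
        res = two_group_compare(x, np.repeat([False, True], 5))
        assert res.p > 0.95

    def test_heavy_tailed_data_fall_back_to_mann_whitney(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.lognormal(0, 1.5, 30), rng.lognormal(0.5, 1.5, 30)])
        res = two_group_compare(x, np.repeat([False, True], 30))
        assert res.test_name == "mann-whitney"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_group_compare([1.0, 2, 3, 4], [False, False, True, True])


class TestScreenMarkers:
    def test_selected_markers_are_planted_ones(self):
        """At the printed effect sizes only a subset of the six planted
        markers survives BH, but false discoveries must stay rare."""
        any_selected = 0
        false_pos = 0
        for seed in range(8):
            table, ann, truth = generate_nci_substudy(seed)
            res = screen_markers(table, ann, alpha=0.05)
            sel = set(res.selected)
            any_selected += bool(sel & set(DISCRIMINATING_MARKERS))
            false_pos += len(sel - set(DISCRIMINATING_MARKERS))
        assert any_selected >= 5
        assert false_pos <= 2

    def test_adjusted_never_below_raw(self, substudy):
        table, ann, _ = substudy
        res = screen_markers(table, ann)
        assert (res.table["q"] >= res.table["p_kw"] - 1e-15).all()
        assert res.table["q"].between(0, 1).all()

    def test_alpha_zero_selects_nothing(self, substudy):
        table, ann, _ = substudy
        res = screen_markers(table, ann, alpha=0.0)
        assert res.selected == []

    def test_two_level_grouping_supported(self, substudy):
        table, ann, _ = substudy
        res = screen_markers(table, ann, grouping="two")
        assert len(res.table) == table.n_markers

    def test_null_cohorts_control_the_fdr(self):
        """With no planted effects, the fraction of cohorts with any
        BH-selected marker stays at or below the nominal 10% level."""
        from immunoprofiles.screen import bh_adjust as bh

        n_any = 0
        n_seeds = 200
        for seed in range(n_seeds):
            table, ann, _ = generate_nci_substudy(seed, plant_effects=False)
            groups = ann.nci_class
            ps = [
                kruskal_wallis(table.values[:, j], groups)[1]
                for j in range(table.n_markers)
            ]
            n_any += (bh(ps) <= 0.05).any()
        assert n_any / n_seeds <= 0.10


class TestWMHCompare:
    def test_marker_lower_in_high_lesion_groups(self, substudy):
        table, ann, _ = substudy
        ann2 = generate_wmh_annotations(table, ann, seed=21)
        res = wmh_compare(table, ann2, "T4_HLADR_pct")
        assert res.periventricular.mean0 > res.periventricular.mean1
        assert res.spearman_r > 0.5

    def test_identical_score_vectors_have_perfect_rank_correlation(self):
        table = make_table(np.arange(24, dtype=float).reshape(12, 2))
        scores = [0, 1, 2, 3, 0, 1, 2, 3, 0, 1, 2, 3]
        ann = make_annotations(
            ["unknown"] * 12, fazekas_pv=scores, fazekas_deep=scores
        )
        res = wmh_compare(table, ann, "m0")
        assert res.spearman_r == pytest.approx(1.0)

    def test_empty_dichotomized_group_is_not_computable(self):
        table = make_table(np.arange(24, dtype=float).reshape(12, 2))
        ann = make_annotations(
            ["unknown"] * 12, fazekas_pv=[0, 1] * 6, fazekas_deep=[2, 3] * 6
        )
        res = wmh_compare(table, ann, "m0")
        assert res.periventricular is None  # nobody scored 2-3
        assert res.deep is None  # nobody scored 0-1

    def test_too_few_rated_patients_rejected(self):
        table = make_table(np.ones((12, 1)))
        ann = make_annotations(["unknown"] * 12)
        with pytest.raises(ValueError, match=">= 10"):
            wmh_compare(table, ann, "m0")


class TestPrevalence:
    def test_published_cohort_arithmetic(self):
        ann = make_annotations(["none"] * 40 + ["ANI"] * 16 + ["MND"] * 9)
        s = prevalence_summary(ann)
        assert s.pct_nci == 38  # 25/65
        assert s.pct_mnd == 14  # 9/65
        assert s.counts == {"none": 40, "ANI": 16, "MND": 9}

    def test_unknowns_excluded_from_denominator(self):
        ann = make_annotations(["none", "ANI", "unknown", "unknown"])
        s = prevalence_summary(ann)
        assert s.pct_nci == 50

    def test_all_controls(self):
        ann = make_annotations(["none"] * 5)
        assert prevalence_summary(ann).pct_nci == 0

    def test_no_classified_patients_is_an_error(self):
        ann = make_annotations(["unknown"] * 3)
        with pytest.raises(ValueError):
            prevalence_summary(ann)
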