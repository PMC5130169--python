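"""Tests for phenotype scoring and the statistical test suite.

The exact tests are checked against independent enumeration oracles and the
scipy reference implementations; the classical tests against their reference
implementations and seeded type-I/power simulations.
"""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gutmap import simulate
from gutmap.stats import (classify_phenotype, compare_groups, count_distal,
                          fisher_exact_2x2, kth_distal_position,
                          significance_stars, spearman_exact, welch_anova_f)
from gutmap.stats import TestResult as StatResult
from gutmap.stats import test_normality as shapiro_wilk
from gutmap.stats import test_variance_homogeneity as brown_forsythe


class TestCountDistal:
    def test_boundary_inclusive(self):
        assert count_distal([0.5, 2.0, 4.9, 5.0, 5.1], 5.0) == 4

    def test_empty(self):
        assert count_distal([], 5.0) == 0

    def test_uniform_expectation(self):
        rng = np.random.default_rng(0)
        counts = [count_distal(rng.uniform(0, 10, 60), 5.0)
                  for _ in range(200)]
        se = math.sqrt(60 * 0.25)                # binomial sd per larva
        assert abs(np.mean(counts) - 30) <= 3 * se / math.sqrt(200)


class TestKthDistal:
    def test_kth_smallest(self):
        assert kth_distal_position([3, 1, 2], 2) == 2.0

    def test_too_few_neurons_missing_with_warning(self):
        with pytest.warns(UserWarning, match="9 neurons"):
            assert math.isnan(kth_distal_position(range(9), 10))

    def test_wt_tenth_neuron_more_distal_than_depleted(self):
        # WT-like guts have neurons to the anal pore; depleted guts lack the
        # most distal ones, pushing the 10th position oralward
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            wt = rng.uniform(0.0, 10.0, 120)
            het = rng.uniform(2.0, 10.0, 60)
            hits += kth_distal_position(wt, 10) < kth_distal_position(het, 10)
        assert hits >= 38


class TestClassifyPhenotype:
    def test_neuron_near_pore_is_np(self):
        assert classify_phenotype(0.4, 100)[0] == "NP"

    def test_severity_strict_threshold(self):
        assert classify_phenotype(0.5, 23)[1] == "severe"
        assert classify_phenotype(0.5, 24)[1] == "not_severe"

    def test_no_neurons_is_phenotypic_and_severe(self):
        assert classify_phenotype(math.nan, 0) == ("P", "severe")


def spearman_oracle(x, y):
    """Exhaustive-permutation Spearman oracle (independent of the package
    implementation): rs from scipy, two-sided p by doubling the tail of the
    permutation distribution of sum(d^2)."""
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    d2_obs = np.sum((rx - ry) ** 2)
    rs = sps.spearmanr(x, y).statistic
    tail = 0
    for perm in itertools.permutations(range(1, n + 1)):
        d2 = np.sum((rx - np.asarray(perm)) ** 2)
        tail += (d2 <= d2_obs) if rs >= 0 else (d2 >= d2_obs)
    return rs, min(1.0, 2.0 * tail / math.factorial(n))


class TestSpearmanExact:
    def test_printed_n6_pair(self):
        # ranks with sum(d^2) = 4 force rs = 1 - 24/210 = 0.8857...
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 3, 4, 6, 5]
        res = spearman_exact(x, y)
        assert res.statistic == pytest.approx(0.8857, abs=5e-5)
        assert res.p_value == pytest.approx(0.0333, abs=5e-5)
        assert res.p_value == pytest.approx(2 * 12 / 720)

    def test_antitone_pair(self):
        res = spearman_exact([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert res.statistic == pytest.approx(-1.0)
        assert res.p_value == pytest.approx(2 / 120)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_agrees_with_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        x = list(range(1, n + 1))
        for _ in range(10):
            y = rng.permutation(n) + 1.0
            res = spearman_exact(x, y)
            rs_o, p_o = spearman_oracle(x, y)
            assert res.statistic == pytest.approx(rs_o)
            assert res.p_value == pytest.approx(p_o)

    def test_ties_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="ties"):
            res = spearman_exact([1, 1, 2, 3, 4], [2, 3, 1, 5, 4])
        ref = sps.spearmanr([1, 1, 2, 3, 4], [2, 3, 1, 5, 4])
        assert res.statistic == pytest.approx(ref.statistic)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            spearman_exact([1, 2], [2, 1])


class TestFisherExact:
    def test_perfect_separation(self):
        res = fisher_exact_2x2([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252)

    def test_homogeneous_table(self):
        assert fisher_exact_2x2([[3, 3], [3, 3]]).p_value == pytest.approx(1.0)

    def test_degenerate_margin_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_2x2([[0, 0], [2, 3]]).p_value == 1.0

    def test_matches_reference_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            t = rng.integers(0, 12, size=(2, 2))
            if min(t.sum(0).min(), t.sum(1).min()) == 0:
                continue
            ours = fisher_exact_2x2(t).p_value
            ref = sps.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, abs=1e-10)


class TestCompareGroups:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        values = np.concatenate([a, b])
        labels = ["a"] * 12 + ["b"] * 15
        res = compare_groups(values, labels, method="anova")
        t = sps.ttest_ind(a, b).statistic
        assert res.statistic == pytest.approx(t ** 2)

    def test_identical_groups_null(self):
        values = [1.0, 2.0, 3.0] * 3
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = compare_groups(values, labels, method="anova")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_matches_reference(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 3, 14),
                                 rng.normal(0.5, 2, 12)])
        labels = ["a"] * 10 + ["b"] * 14 + ["c"] * 12
        f, df1, df2 = welch_anova_f([values[:10], values[10:24], values[24:]])
        ref = pingouin.welch_anova(
            pd.DataFrame({"v": values, "g": labels}), dv="v", between="g")
        assert f == pytest.approx(ref["F"][0], abs=1e-6)
        assert df2 == pytest.approx(ref["ddof2"][0], abs=1e-6)
        res = compare_groups(values, labels, method="welch_anova")
        assert res.p_value == pytest.approx(ref["p_unc"][0], abs=1e-6)

    def test_bonferroni_adjustment_bounds(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(i, 1, 10) for i in range(3)])
        labels = sum([[g] * 10 for g in "abc"], [])
        res = compare_groups(values, labels, method="anova",
                             posthoc="bonferroni")
        assert len(res.pairwise) == 3
        for pw in res.pairwise:
            raw = float(pw.note.split("=")[1])
            assert pw.p_value >= raw - 1e-15
            assert 0 <= pw.p_value <= 1

    def test_tukey_posthoc_runs(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(i, 1, 10) for i in range(3)])
        labels = sum([[g] * 10 for g in "abc"], [])
        res = compare_groups(values, labels, method="anova", posthoc="tukey")
        assert len(res.pairwise) == 3
        assert all(0 <= pw.p_value <= 1 for pw in res.pairwise)

    def test_undersized_group_named_in_error(self):
        with pytest.raises(ValueError, match="'b'"):
            compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestNormalityAndVariance:
    def test_shapiro_matches_reference(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 50)
        res = shapiro_wilk(x)
        w, p = sps.shapiro(x)
        assert res.statistic == pytest.approx(w, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk([1.0] * 10)

    def test_brown_forsythe_matches_reference(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 3, 30)
        res = brown_forsythe(np.concatenate([a, b]),
                             ["a"] * 30 + ["b"] * 30)
        stat, p = sps.levene(a, b, center="median")
        assert res.statistic == pytest.approx(stat, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_brown_forsythe_power_on_ninefold_variance(self):
        reject = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a, b = rng.normal(0, 1, 50), rng.normal(0, 3, 50)
            res = brown_forsythe(np.concatenate([a, b]),
                                 ["a"] * 50 + ["b"] * 50)
            reject += res.p_value < 0.05
        assert reject > 90

    def test_shapiro_power_on_bimodal_mixture(self):
        grp = simulate.GroupSpec("mix", ("mixture", 0.5, 10.0, 5.0, 70.0, 5.0))
        reject = 0
        for seed in range(100):
            table, _ = simulate.simulate_cohort(
                simulate.CohortSimConfig(groups=(grp,), n_per_group=200,
                                         seed=seed))
            res = shapiro_wilk(table["distal_count"])
            reject += res.p_value < 0.05
        assert reject > 95

    def test_shapiro_type_i_non_rejection(self):
        rng = np.random.default_rng(8)
        non_reject = sum(shapiro_wilk(rng.normal(0, 1, 200)).p_value >= 0.05
                         for _ in range(100))
        assert non_reject >= 90


class TestSeverityPipeline:
    def test_mixture_group_has_more_severe_larvae(self):
        hits = 0
        for seed in range(100):
            cfg = simulate.CohortSimConfig(
                groups=(simulate.ret_het_like_group("A"),
                        simulate.ret_het_modifier_group("B")),
                n_per_group=30, seed=seed)
            table, _ = simulate.simulate_cohort(cfg)
            frac = {g: (grp["distal_count"] < 24).mean()
                    for g, grp in table.groupby("genotype")}
            hits += frac["B"] > frac["A"]
        assert hits >= 99


class TestResultContracts:
    def test_p_value_range_enforced(self):
        with pytest.raises(ValueError):
            StatResult("x", 0.0, 1.5)

    def test_significance_star_grading(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.00004) == "****"


class TestExactTestProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.permutations(list(range(1, 7))))
    def test_spearman_symmetric_with_valid_p(self, y):
        x = list(range(1, 7))
        r_xy = spearman_exact(x, y)
        r_yx = spearman_exact(y, x)
        assert 0.0 <= r_xy.p_value <= 1.0
        assert r_xy.statistic == pytest.approx(r_yx.statistic)
        assert r_xy.p_value == pytest.approx(r_yx.p_value)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 10)] * 4))
    def test_fisher_transpose_invariant(self, cells):
        a, b, c, d = cells
        t = np.array([[a, b], [c, d]])
        assume(min(t.sum(0).min(), t.sum(1).min()) > 0)
        p1 = fisher_exact_2x2(t).p_value
        p2 = fisher_exact_2x2(t.T).p_value
        assert 0.0 <= p1 <= 1.0
        assert p1 == pytest.approx(p2, abs=1e-12)
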