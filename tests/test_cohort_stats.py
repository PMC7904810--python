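"""Fisher, Wilcoxon and Spearman against enumeration oracles and scipy."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neotel.cohort_stats import (
    COHORT_PRESETS,
    TwoByTwo,
    cohort_fisher_tests,
    fisher_exact_two_sided,
    positive_fraction,
    spearman,
    wilcoxon_rank_sum_two_sided,
)

counts = st.integers(min_value=0, max_value=40)


# published two-sided Fisher p-values for the preset cohort tables, with a
# relative tolerance matched to each value's printed precision
PRINTED_P = {
    ("screening", "stage_1_3_vs_4"): (1.948e-06, 1e-3),
    ("screening", "stage_4s_vs_other"): (0.000367, 5e-3),
    ("screening", "risk_lr_ir_vs_hr"): (6.944e-07, 1e-3),
    ("screening", "sex_male_vs_female"): (0.519, 5e-3),
    ("screening", "mycn_amp_vs_normal"): (5.883e-06, 1e-3),
    ("screening", "ganglioneuroma_vs_other"): (0.6115, 1e-3),
    ("inform", "stage_1_3_vs_4"): (0.041, 2.5e-2),
    ("inform", "stage_4s_vs_other"): (1.000, 1e-3),
    ("inform", "risk_lr_ir_vs_hr"): (0.226, 5e-3),
    ("inform", "sex_male_vs_female"): (0.120, 5e-3),
    ("inform", "mycn_amp_vs_normal"): (0.029, 2.5e-2),
}


class TestFisher:
    @pytest.mark.parametrize("cohort,contrast", sorted(PRINTED_P))
    def test_preset_tables_reproduce_published_p_values(self, cohort, contrast):
        table = COHORT_PRESETS[cohort][contrast]
        _, p = fisher_exact_two_sided(table)
        printed, rel = PRINTED_P[(cohort, contrast)]
        assert p == pytest.approx(printed, rel=rel)

    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided(TwoByTwo(1, 1, 1, 1))[1] == 1.0

    def test_extreme_table_matches_enumeration(self):
        _, p = fisher_exact_two_sided(TwoByTwo(0, 10, 10, 0))
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    def test_zero_margin_gives_one(self):
        assert fisher_exact_two_sided(TwoByTwo(0, 0, 5, 7))[1] == 1.0
        assert fisher_exact_two_sided(TwoByTwo(0, 5, 0, 7))[1] == 1.0

    @given(counts, counts, counts, counts)
    @settings(max_examples=150, deadline=None)
    def test_invariance_under_row_and_column_swap(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(TwoByTwo(a, b, c, d))[1]
        assert 0.0 < p <= 1.0
        assert fisher_exact_two_sided(TwoByTwo(c, d, a, b))[1] == pytest.approx(p)
        assert fisher_exact_two_sided(TwoByTwo(b, a, d, c))[1] == pytest.approx(p)

    @given(counts, counts, counts, counts)
    @settings(max_examples=150, deadline=None)
    def test_agreement_with_scipy_reference(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(TwoByTwo(a, b, c, d))[1]
        p_ref = stats.fisher_exact([[a, b], [c, d]])[1]
        assert p == pytest.approx(p_ref, rel=1e-6, abs=1e-12)

    def test_sample_odds_ratio(self):
        odds, _ = fisher_exact_two_sided(TwoByTwo(10, 5, 2, 8))
        assert odds == pytest.approx(8.0)
        assert math.isinf(fisher_exact_two_sided(TwoByTwo(5, 0, 2, 8))[0])


def _wilcoxon_enumeration_oracle(x, y):
    """Exact two-sided p by full enumeration of group assignments.

    Doubles the smaller tail probability of the rank-sum statistic
    (including the point mass), capped at 1.
    """
    pooled = sorted(x) + sorted(y)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    n, m = len(x), len(y)
    w_obs = sum(ranks[v] for v in x)
    lower = higher = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        w = sum(ranks[pooled[i]] for i in combo)
        total += 1
        lower += w <= w_obs
        higher += w >= w_obs
    return min(1.0, 2 * min(lower, higher) / total)


class TestWilcoxon:
    def test_separated_triplets_exact_p(self):
        assert wilcoxon_rank_sum_two_sided([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_give_one(self):
        assert wilcoxon_rank_sum_two_sided([2.0, 2.0], [2.0, 2.0]) == 1.0
        assert wilcoxon_rank_sum_two_sided([1, 2, 3], [1, 2, 3]) == 1.0

    @pytest.mark.parametrize("n,m,seed", [(3, 3, 0), (4, 5, 1), (6, 6, 2), (5, 7, 3)])
    def test_exact_branch_equals_full_enumeration(self, n, m, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(loc=0.8, size=m)
        p = wilcoxon_rank_sum_two_sided(x, y)
        assert p == pytest.approx(_wilcoxon_enumeration_oracle(list(x), list(y)))

    def test_exact_and_normal_branches_agree_on_tie_free_n40(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            x = rng.normal(size=20)
            y = rng.normal(loc=0.3, size=20)
            p_exact = wilcoxon_rank_sum_two_sided(x, y)
            p_norm = wilcoxon_rank_sum_two_sided(x, y, exact_max_n=0)
            assert abs(p_exact - p_norm) < 0.005

    def test_shift_alternative_power_near_theory(self):
        """n=50/50, 1 SD shift: rejection rate close to theoretical power."""
        rng = np.random.default_rng(23)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(size=50)
            y = rng.normal(loc=1.0, size=50)
            rejections += wilcoxon_rank_sum_two_sided(x, y) < 0.05
        # theoretical power of the rank-sum test here is ~0.999
        assert rejections / n_rep > 0.97

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum_two_sided([], [1.0])


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [10, 20, 30, 40, 50]) == pytest.approx(1.0)
        assert spearman(x, [50, 40, 30, 20, 10]) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=10)
        y = x + rng.normal(scale=0.8, size=10)
        oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert spearman(x, y) == pytest.approx(oracle)

    def test_zero_variance_undefined(self):
        assert spearman([1, 1, 1], [1, 2, 3]) is None


class TestCohortSummaries:
    def test_positive_fractions_match_published_percentages(self):
        assert round(100 * positive_fraction("screening"), 1) == 9.2
        assert round(100 * positive_fraction("inform"), 1) == 47.5

    def test_preset_margins_are_consistent(self):
        # contrasts never exceed the cohort's C-Circle group sizes (some
        # tumors lack staging, risk or MYCN information)
        for t in COHORT_PRESETS["screening"].values():
            assert t.a + t.b <= 66 and t.c + t.d <= 654
        for t in COHORT_PRESETS["inform"].values():
            assert t.a + t.b <= 19 and t.c + t.d <= 21

    def test_cohort_fisher_tests_cover_all_contrasts(self):
        res = cohort_fisher_tests("screening")
        assert set(res) == set(COHORT_PRESETS["screening"])
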