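"""Statistical battery: Fisher, Wilcoxon, age bins, hypergeometric group
test, Pearson test, complex co-membership tables."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from dupred.errors import ValidationError
from dupred.stats import (
    AgeBin,
    ContingencyTable2x2,
    age_group_hypergeom_test,
    complex_comembership_table,
    fisher_exact_2x2,
    pearson_correlation_test,
    stratify_by_age,
    wilcoxon_rank_sum,
)

from oracles import fisher_oracle, hypergeom_term_oracle, wilcoxon_exact_oracle


# ---- Fisher ---------------------------------------------------------------


def test_fisher_symmetric_table():
    odds, p = fisher_exact_2x2((5, 5, 5, 5))
    assert odds == 1.0
    assert p == pytest.approx(1.0)


def test_fisher_extreme_table_closed_form():
    odds, p = fisher_exact_2x2((10, 0, 0, 10))
    assert math.isinf(odds)
    assert p == pytest.approx(2.0 / 184756.0, rel=1e-9)


def test_fisher_odds_ratio_edge_cases():
    odds, _ = fisher_exact_2x2((0, 5, 0, 5))
    assert math.isnan(odds)
    odds, _ = fisher_exact_2x2((5, 0, 1, 5))
    assert math.isinf(odds)


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValidationError):
        fisher_exact_2x2((-1, 2, 3, 4))
    with pytest.raises(ValidationError):
        ContingencyTable2x2(0, 0, 0, 0)


@pytest.mark.parametrize("seed", range(5))
def test_fisher_matches_enumeration_and_scipy(seed):
    rng = np.random.default_rng(seed)
    for _ in range(20):
        a, b, c, d = (int(v) for v in rng.integers(0, 12, 4))
        if a + b + c + d == 0:
            continue
        odds, p = fisher_exact_2x2((a, b, c, d))
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)
        _, p_scipy = sps.fisher_exact([[a, b], [c, d]])
        assert p == pytest.approx(p_scipy, abs=1e-9)


# ---- Wilcoxon -------------------------------------------------------------


def test_wilcoxon_small_sample_exact():
    stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1)


def test_wilcoxon_identical_samples():
    _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert p > 0.9


def test_wilcoxon_missing_values_dropped_and_empty_rejected():
    _, p = wilcoxon_rank_sum([1, 2, 3, math.nan], [4, 5, 6])
    assert p == pytest.approx(0.1)
    with pytest.raises(ValidationError):
        wilcoxon_rank_sum([math.nan], [1, 2])


@pytest.mark.parametrize("seed", range(5))
def test_wilcoxon_exact_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    n, m = int(rng.integers(3, 8)), int(rng.integers(3, 8))
    values = rng.permutation(100)[: n + m].astype(float)
    x, y = list(values[:n]), list(values[n:])
    _, p = wilcoxon_rank_sum(x, y)
    assert p == pytest.approx(wilcoxon_exact_oracle(x, y), abs=1e-12)


def test_wilcoxon_normal_approximation_close_to_exact():
    rng = np.random.default_rng(7)
    diffs = []
    for _ in range(10):
        values = rng.permutation(1000)[:16].astype(float)
        x, y = list(values[:8]), list(values[8:])
        p_exact = wilcoxon_exact_oracle(x, y)
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        diffs.append(abs(res.pvalue - p_exact))
    # continuity-corrected normal approximation tracks the exact p closely
    assert max(diffs) < 0.02
    assert float(np.mean(diffs)) < 0.01


# ---- age bins and group test ----------------------------------------------


def _bins(pairs):
    """pairs: list of (age, is_md, value)"""
    ages, md, values = zip(*pairs)
    return stratify_by_age(ages, md, values)


def test_single_age_gives_single_bin():
    bins = _bins([(90, True, 1.0)] * 3 + [(90, False, 0.5)] * 3)
    assert len(bins) == 1
    assert bins[0].is_valid()


def test_three_ages_three_valid_bins():
    pairs = []
    for age in (0, 90, 100):
        pairs += [(age, True, 1.0)] * 3 + [(age, False, 0.5)] * 3
    bins = _bins(pairs)
    assert len(bins) == 3
    assert all(b.is_valid() for b in bins)


def test_underfilled_bin_marked_invalid():
    pairs = [(90, True, 1.0)] * 2 + [(90, False, 0.5)] * 3
    pairs += [(100, True, 1.0)] * 3 + [(100, False, 0.5)] * 3
    bins = _bins(pairs)
    invalid = [b for b in bins if not b.is_valid()]
    assert len(invalid) == 1 and invalid[0].age == 90
    assert len(invalid[0].md_values) == 2


def test_no_valid_bins_raises():
    with pytest.raises(ValidationError):
        _bins([(90, True, 1.0), (90, False, 0.5)])


def _make_bins(md_means, nd_means):
    return [
        AgeBin(age=i, md_values=[m] * 3, nd_values=[n] * 3)
        for i, (m, n) in enumerate(zip(md_means, nd_means))
    ]


def test_group_test_all_bins_md_higher():
    bins = _make_bins([1.0] * 10, [0.0] * 10)
    q, K, p = age_group_hypergeom_test(bins)
    assert (q, K) == (10, 10)
    assert p == pytest.approx(hypergeom_term_oracle(10, 10), rel=1e-9)
    assert p == pytest.approx(1.0 / 184756.0, rel=1e-9)


def test_group_test_lower_tail_symmetry():
    bins = _make_bins([0.0] * 10, [1.0] * 10)
    q, K, p = age_group_hypergeom_test(bins, tail="lower")
    assert q == 0
    assert p == pytest.approx(hypergeom_term_oracle(10, 0), rel=1e-9)


def test_group_test_ties_count_against_q():
    bins = _make_bins([1.0] * 5 + [0.5] * 5, [0.5] * 10)
    q, K, p = age_group_hypergeom_test(bins)
    assert q == 5 and K == 10


def test_group_test_distribution_sums_to_one():
    for K in (5, 8, 12):
        total = sum(hypergeom_term_oracle(K, q) for q in range(K + 1))
        assert total == pytest.approx(1.0, rel=1e-12)
        dist = sps.hypergeom(2 * K, K, K)
        assert sum(dist.pmf(q) for q in range(K + 1)) == pytest.approx(1.0)


def test_group_test_midpoint_matches_enumeration():
    K = 10
    bins = _make_bins([1.0] * 5 + [0.0] * 5, [0.5] * 10)
    q, _, p = age_group_hypergeom_test(bins)
    assert q == 5
    expected = sum(hypergeom_term_oracle(K, j) for j in range(5, K + 1))
    assert p == pytest.approx(expected, rel=1e-9)


def test_group_test_requires_enough_bins():
    with pytest.raises(ValidationError, match="too few"):
        age_group_hypergeom_test(_make_bins([1.0] * 4, [0.0] * 4))


def test_group_test_md_lower_direction():
    bins = _make_bins([0.0] * 10, [1.0] * 10)
    q, _, p = age_group_hypergeom_test(bins, direction="md_lower")
    assert q == 10
    assert p == pytest.approx(1.0 / 184756.0, rel=1e-9)


# ---- Pearson test ---------------------------------------------------------


def test_pearson_perfect_line():
    r, p = pearson_correlation_test([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
    assert r == pytest.approx(1.0)
    assert p < 1e-6


def test_pearson_hand_dataset():
    """x=(1,2,3,4), y=(2,1,4,3): r=0.6, t=r*sqrt(2)/sqrt(1-r^2); for 2 df
    the t CDF has the closed form 1/2 + t/(2*sqrt(2+t^2)), giving p=0.4."""
    r, p = pearson_correlation_test([1, 2, 3, 4], [2, 1, 4, 3])
    assert r == pytest.approx(0.6)
    assert p == pytest.approx(0.4, abs=1e-9)


def test_pearson_null_p_values_uniform():
    rng = np.random.default_rng(11)
    hits = 0
    reps = 4000
    for _ in range(reps):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        _, p = pearson_correlation_test(x, y)
        hits += p < 0.05
    assert abs(hits / reps - 0.05) < 0.012


def test_pearson_zero_variance_rejected():
    with pytest.raises(ValidationError):
        pearson_correlation_test([1, 1, 1, 1], [1, 2, 3, 4])


# ---- complex co-membership ------------------------------------------------

COMPLEXES = {"C1": {"a1", "a2", "b1"}, "C2": {"c1", "c2"}, "C3": {"d1"}}


def test_comember_pair_detection():
    table = complex_comembership_table(
        [("a1", "a2")], [("c1", "d1")], COMPLEXES
    )
    assert (table.a, table.b) == (1, 0)  # co-member
    assert (table.c, table.d) == (0, 1)  # disjoint complexes


def test_unannotated_pairs_count_as_not_comember():
    table = complex_comembership_table([("x", "y")], [("c1", "c2")], COMPLEXES)
    assert (table.a, table.b) == (0, 1)


def test_comembership_toy_table_and_odds_ratio():
    md = [("a1", "a2")] + [("x", f"y{i}") for i in range(3)]
    nd = [("a1", "b1"), ("c1", "c2"), ("a2", "b1"), ("x", "z")]
    table = complex_comembership_table(md, nd, COMPLEXES)
    assert (table.a, table.b, table.c, table.d) == (1, 3, 3, 1)
    odds, _ = fisher_exact_2x2(table)
    assert odds == pytest.approx(1.0 / 9.0)


def test_empty_complexes_rejected():
    with pytest.raises(ValidationError):
        complex_comembership_table([("a", "b")], [("c", "d")], {})
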