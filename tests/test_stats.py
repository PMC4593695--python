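"""Correlation suite, Fisher-z comparison, top-k overlap machinery."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concordia import (
    FoldChangeTable,
    compare_correlations_fisher_z,
    correlation_suite,
    overlap_exact_pvalue,
    overlap_null_distribution,
    overlap_permutation_test,
    pairwise_correlations,
    reproducibility_report,
    threshold_concordance,
    top_k_list,
)


def fc_table(mapping, source="t"):
    return FoldChangeTable(source, pd.Series(mapping))


# ------------------------------------------------------ correlation suite

def test_identical_vectors_correlate_perfectly():
    c = correlation_suite([1.0, 2.0, 5.0, 9.0], [1.0, 2.0, 5.0, 9.0])
    assert c.pearson == pytest.approx(1.0)
    assert c.pearson_log2 == pytest.approx(1.0)
    assert c.spearman == pytest.approx(1.0)
    assert c.n == 4


def test_hand_computed_rank_example():
    c = correlation_suite([1, 2, 3, 4], [1, 3, 2, 4])
    assert c.pearson == pytest.approx(0.8)
    assert c.spearman == pytest.approx(0.8)


def test_spearman_unchanged_by_monotone_and_log_transform():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.exp2(x)  # monotone but nonlinear
    c = correlation_suite(x, y)
    assert c.spearman == pytest.approx(1.0)
    c_log = correlation_suite(x, np.log2(y))
    assert c_log.spearman == pytest.approx(c.spearman)


@given(
    st.lists(st.integers(1, 100_000), min_size=4, max_size=20, unique=True),
    st.floats(0.1, 5.0),
    st.floats(0.01, 10.0),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_spearman_invariant_under_increasing_transforms(xs, power, scale):
    xs = np.array(xs, dtype=float)
    rng = np.random.default_rng(0)
    ys = rng.permutation(xs)
    base = correlation_suite(xs, ys)
    transformed = correlation_suite(xs ** power * scale, ys)
    assert transformed.spearman == pytest.approx(base.spearman, abs=1e-9)


def test_non_positive_values_rejected_with_count():
    with pytest.raises(ValueError, match="2 non-positive"):
        correlation_suite([1.0, -1.0, 2.0, 0.0], [1.0, 2.0, 3.0, 4.0])


def test_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        correlation_suite([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ----------------------------------------------------------- Fisher's z

def test_equal_correlations_give_zero_z_unit_p():
    z, p = compare_correlations_fisher_z(0.5, 50, 0.5, 80)
    assert z == 0.0 and p == 1.0


def test_qpcr_sized_comparison_is_not_significant():
    # r=0.56 vs r=0.48 on 76 genes each: z ~= 0.664, p well above 0.05
    z, p = compare_correlations_fisher_z(0.56, 76, 0.48, 76)
    expected_z = (math.atanh(0.56) - math.atanh(0.48)) / math.sqrt(2 / 73)
    assert z == pytest.approx(expected_z)
    assert z == pytest.approx(0.664, abs=5e-4)
    assert p > 0.05


def test_degenerate_correlation_rejected():
    with pytest.raises(ValueError):
        compare_correlations_fisher_z(1.0, 10, 0.5, 10)


# -------------------------------------------------------------- top-k

def test_top_k_highest_and_lowest():
    t = fc_table({"a": 5.0, "b": 2.0, "c": 9.0})
    assert top_k_list(t, 2, "highest") == ["c", "a"]
    assert top_k_list(t, 2, "lowest") == ["b", "a"]


def test_top_k_ties_break_lexicographically():
    t = fc_table({"p2": 5.0, "p10": 5.0, "p3": 1.0})
    assert top_k_list(t, 2, "highest") == ["p10", "p2"]  # "p10" < "p2"


def test_top_k_rejects_oversized_k():
    with pytest.raises(ValueError):
        top_k_list(fc_table({"a": 1.0}), 2)


# -------------------------------------------------- overlap permutation

def test_exact_pvalue_worked_examples():
    assert overlap_exact_pvalue(5, 0, 20) == 1.0
    # 1 - C(15,5)/C(20,5) - 5*C(15,4)/C(20,5)
    assert overlap_exact_pvalue(5, 2, 20) == pytest.approx(0.366099, abs=1e-6)
    assert overlap_exact_pvalue(7, 3, 7) == 1.0  # k = N forces full overlap


def test_zero_observed_overlap_means_p_one():
    a = [f"x{i}" for i in range(5)]
    b = [f"y{i}" for i in range(5)]
    res = overlap_permutation_test(a, b, universe_size=100, n_trials=200, seed=3)
    assert res.n_observed == 0
    assert res.p_value == 1.0


def test_identical_lists_are_essentially_impossible_under_null():
    a = [f"g{i}" for i in range(5)]
    res = overlap_permutation_test(a, a, universe_size=1000, n_trials=5000, seed=9)
    assert res.n_observed == 5
    assert res.p_value == 0.0  # hypergeometric point mass ~ 1e-13


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        overlap_permutation_test(["a", "a"], ["b", "c"], 10)


def test_empirical_matches_exact_tail():
    n_trials = 10_000
    null = overlap_null_distribution(5, 30, n_trials, seed=21)
    for n in range(6):
        exact = overlap_exact_pvalue(5, n, 30)
        emp = (null >= n).mean()
        se = math.sqrt(exact * (1 - exact) / n_trials)
        assert abs(emp - exact) <= 3 * se + 1e-12


def test_pvalue_nonincreasing_in_observed_overlap():
    null = overlap_null_distribution(10, 100, 2000, seed=5)
    ps = [(null >= n).mean() for n in range(11)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))
    exact = [overlap_exact_pvalue(10, n, 100) for n in range(11)]
    assert all(a >= b for a, b in zip(exact, exact[1:]))


# ------------------------------------------------- threshold concordance

def test_threshold_concordance_enumeration():
    a = fc_table({"p1": 6.0, "p2": 10.0, "p3": 2.0, "p4": 0.5}, "a")
    b = fc_table({"p1": 7.0, "p2": 1.0, "p3": 9.0, "p4": 0.1}, "b")
    r = threshold_concordance(a, b, 5.0)
    assert (r.n_a_above, r.n_both_above, r.percent) == (2, 1, 50.0)


def test_threshold_concordance_identical_tables():
    a = fc_table({"p1": 6.0, "p2": 1.0}, "a")
    r = threshold_concordance(a, a, 5.0)
    assert r.percent == 100.0


def test_threshold_above_everything_reports_nan():
    a = fc_table({"p1": 2.0, "p2": 1.0}, "a")
    r = threshold_concordance(a, a, 99.0)
    assert r.n_a_above == 0 and math.isnan(r.percent)


# ------------------------------------------------------ pairwise grids

def test_four_sources_give_six_pairs():
    rng = np.random.default_rng(2)
    tables = {
        f"QP{i}": fc_table(dict(zip("abcdefgh", np.exp(rng.normal(0, 1, 8)))), f"QP{i}")
        for i in range(1, 5)
    }
    report = reproducibility_report(tables)
    assert len(report) == 6


def test_pair_correlations_are_symmetric():
    rng = np.random.default_rng(8)
    v = {
        "A": pd.Series(np.exp(rng.normal(0, 1, 10)), index=[f"p{i}" for i in range(10)]),
        "B": pd.Series(np.exp(rng.normal(0, 1, 10)), index=[f"p{i}" for i in range(10)]),
    }
    ab = pairwise_correlations(v)[("A", "B")]
    ba = pairwise_correlations({"B": v["B"], "A": v["A"]})[("B", "A")]
    assert ab.pearson == pytest.approx(ba.pearson)
    assert ab.spearman == pytest.approx(ba.spearman)
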