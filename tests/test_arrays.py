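"""Two-channel array processing: unmixing, MA-LOWESS, fold changes, swaps."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concordia import (
    ArrayScan,
    FoldChangeTable,
    array_fold_changes,
    combine_arrays_geometric_mean,
    correlation_suite,
    cross_channel_correct,
    lowess_normalize,
    swap_orientation,
)


def make_scan(cy3, cy5, excluded=None, orientation="qui-cy5", array_id="A"):
    df = pd.DataFrame(
        {"cy3": cy3, "cy5": cy5},
        index=[f"p{i:03d}" for i in range(len(cy3))],
    )
    if excluded is not None:
        df["excluded"] = excluded
    return ArrayScan(array_id, orientation, df)


# ------------------------------------------------------- crosstalk unmixing

def test_unmixing_identity_at_alpha_zero():
    scan = make_scan([10.0, 20.0], [30.0, 40.0])
    out = cross_channel_correct(scan, 0.0)
    pd.testing.assert_frame_equal(out.data[["cy3", "cy5"]], scan.data[["cy3", "cy5"]])


def test_unmixing_recovers_worked_example():
    # observed (105, 60) under alpha=0.1 unmixes to clean (100, 50)
    scan = make_scan([105.0], [60.0])
    out = cross_channel_correct(scan, 0.1)
    assert out.data["cy3"].iloc[0] == pytest.approx(100.0, abs=1e-12)
    assert out.data["cy5"].iloc[0] == pytest.approx(50.0, abs=1e-12)


@given(alpha=st.floats(0.0, 0.49), a=st.floats(0.1, 1e6), b=st.floats(0.1, 1e6))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_unmixing_inverts_mixing_for_any_alpha(alpha, a, b):
    mixed = make_scan([a + alpha * b], [b + alpha * a])
    out = cross_channel_correct(mixed, alpha)
    assert out.data["cy3"].iloc[0] == pytest.approx(a, rel=1e-9)
    assert out.data["cy5"].iloc[0] == pytest.approx(b, rel=1e-9)


def test_unmixing_rejects_alpha_at_least_half():
    scan = make_scan([1.0], [1.0])
    with pytest.raises(ValueError):
        cross_channel_correct(scan, 0.5)


def test_unmixing_floors_and_flags_negatives():
    scan = make_scan([1.0], [100.0])  # cy3 - 0.3*cy5 < 0
    out = cross_channel_correct(scan, 0.3)
    assert out.data["cy3"].iloc[0] > 0
    assert bool(out.data["floored"].iloc[0])


# ------------------------------------------------------------- MA-LOWESS

def test_lowess_removes_constant_log_ratio_exactly():
    rng = np.random.default_rng(0)
    cy3 = rng.uniform(50, 5000, size=200)
    scan = make_scan(cy3, cy3 * 4.0)  # M = 2 everywhere
    out = lowess_normalize(scan)
    m = np.log2(out.data["cy5"] / out.data["cy3"])
    np.testing.assert_allclose(m, 0.0, atol=1e-9)


def test_lowess_centres_multiplicative_dye_bias():
    rng = np.random.default_rng(42)
    base = np.exp2(rng.normal(8, 2, size=5000))
    noise = np.exp(rng.normal(0, 0.2, size=5000))
    scan = make_scan(base, base * 1.7 * noise)  # 1.7x dye bias on cy5
    out = lowess_normalize(scan)
    m = np.log2(out.data["cy5"] / out.data["cy3"])
    assert abs(np.median(m)) < 0.01


def test_lowess_preserves_mean_log_intensity():
    rng = np.random.default_rng(3)
    cy3 = rng.uniform(10, 1000, 500)
    cy5 = rng.uniform(10, 1000, 500)
    scan = make_scan(cy3, cy5)
    out = lowess_normalize(scan)
    a_before = 0.5 * np.log2(cy3 * cy5)
    a_after = 0.5 * np.log2(out.data["cy3"] * out.data["cy5"])
    np.testing.assert_allclose(a_after, a_before, atol=1e-9)


def test_lowess_idempotent_once_trend_removed():
    rng = np.random.default_rng(5)
    cy3 = rng.uniform(50, 5000, 300)
    scan = make_scan(cy3, cy3 * 2.5)  # constant trend: fully removed in one pass
    once = lowess_normalize(scan)
    twice = lowess_normalize(once)
    np.testing.assert_allclose(
        twice.data[["cy3", "cy5"]], once.data[["cy3", "cy5"]], atol=1e-6
    )


def test_lowess_needs_enough_probes():
    scan = make_scan([1.0] * 5, [2.0] * 5)
    with pytest.raises(ValueError, match="retained probes"):
        lowess_normalize(scan)


# ------------------------------------------------------------ fold changes

def test_fold_change_of_known_channels():
    scan = make_scan([50.0], [200.0], orientation="qui-cy5")
    fc = array_fold_changes(scan)
    assert fc.fc.iloc[0] == pytest.approx(4.0)
    assert fc.log2_fc.iloc[0] == pytest.approx(2.0)


def test_excluded_probes_absent_from_fold_changes():
    scan = make_scan([10.0, 10.0], [20.0, 20.0], excluded=[False, True])
    assert list(array_fold_changes(scan).fc.index) == ["p000"]


def test_zero_pro_channel_probe_dropped():
    scan = make_scan([0.0, 10.0], [20.0, 20.0], orientation="qui-cy5")
    assert list(array_fold_changes(scan).fc.index) == ["p001"]


def test_swap_orientation_is_involution_and_reciprocal():
    scan = make_scan([50.0, 80.0], [200.0, 20.0])
    fc = array_fold_changes(scan)
    swapped_fc = array_fold_changes(swap_orientation(scan))
    np.testing.assert_allclose(swapped_fc.fc, 1.0 / fc.fc)
    back = array_fold_changes(swap_orientation(swap_orientation(scan)))
    pd.testing.assert_series_equal(back.fc, fc.fc)


def test_swap_negates_log_fold_change_correlation():
    rng = np.random.default_rng(11)
    scan = make_scan(rng.uniform(10, 1000, 50), rng.uniform(10, 1000, 50))
    fc = array_fold_changes(scan)
    swapped = array_fold_changes(swap_orientation(scan))
    c = correlation_suite(fc.fc.to_numpy(), swapped.fc.to_numpy())
    assert c.pearson_log2 == pytest.approx(-1.0, abs=1e-12)


# -------------------------------------------------------- geometric mean

def test_geometric_mean_worked_examples():
    t = lambda label, vals: FoldChangeTable(label, pd.Series(vals, index=["p1"]))
    assert combine_arrays_geometric_mean([t("a", [2.0]), t("b", [8.0])]).fc.iloc[0] == pytest.approx(4.0)
    assert combine_arrays_geometric_mean([t(str(i), [1.0]) for i in range(4)]).fc.iloc[0] == pytest.approx(1.0)
    vals = [2.0, 8.0, 4.0, 1.0]
    combined = combine_arrays_geometric_mean([t(str(i), [v]) for i, v in enumerate(vals)])
    assert combined.fc.iloc[0] == pytest.approx(64 ** 0.25)


@given(
    st.lists(
        st.lists(st.floats(0.01, 100.0), min_size=3, max_size=3),
        min_size=2,
        max_size=4,
    )
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_geometric_mean_commutes_with_reciprocal(fc_lists):
    tables = [
        FoldChangeTable(str(i), pd.Series(vals, index=["p1", "p2", "p3"]))
        for i, vals in enumerate(fc_lists)
    ]
    combined = combine_arrays_geometric_mean(tables)
    combined_recip = combine_arrays_geometric_mean([t.reciprocal() for t in tables])
    np.testing.assert_allclose(combined_recip.fc, 1.0 / combined.fc, rtol=1e-9)


def test_non_positive_fold_changes_rejected():
    with pytest.raises(ValueError):
        FoldChangeTable("bad", pd.Series([1.0, 0.0], index=["a", "b"]))
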