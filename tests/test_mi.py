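"""Unit and property tests for the B-spline MI estimator and its
permutation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from etnet import (MIEstimatorConfig, bspline_weights, mutual_information,
                   permutation_test_independence, permutation_test_mi_difference,
                   select_bins, standardize)


# ------------------------------------------------------------- standardize

def test_standardize_rows_have_zero_mean_unit_sd():
    df = pd.DataFrame([[1.0, 2.0, 3.0], [10.0, 0.0, 5.0]], index=["a", "b"])
    out, excluded = standardize(df)
    assert excluded == []
    assert np.allclose(out.mean(axis=1), 0)
    assert np.allclose(out.std(axis=1, ddof=1), 1)
    # idempotent up to tolerance
    out2, _ = standardize(out)
    assert np.allclose(out, out2)


def test_standardize_excludes_constant_rows_with_report():
    df = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
    out, excluded = standardize(df)
    assert excluded == ["flat"]
    assert list(out.index) == ["ok"]


def test_standardize_rejects_nonfinite():
    df = pd.DataFrame([[1.0, np.nan, 3.0]])
    with pytest.raises(ValueError, match="non-finite"):
        standardize(df)


# --------------------------------------------------------- B-spline basis

def _cox_de_boor(pos: float, t: np.ndarray, k: int, i: int) -> float:
    """Independent order-k basis evaluation by the textbook recursion."""
    if k == 1:
        return 1.0 if t[i] <= pos < t[i + 1] else 0.0
    left = 0.0
    if t[i + k - 1] > t[i]:
        left = (pos - t[i]) / (t[i + k - 1] - t[i]) * _cox_de_boor(pos, t, k - 1, i)
    right = 0.0
    if t[i + k] > t[i + 1]:
        right = (t[i + k] - pos) / (t[i + k] - t[i + 1]) * _cox_de_boor(pos, t, k - 1, i + 1)
    return left + right


def test_order1_weights_are_histogram_indicators():
    x = np.array([0.0, 0.1, 0.49, 0.51, 0.99, 1.0])
    W = bspline_weights(x, k=1, M=2)
    assert W.shape == (6, 2)
    assert set(map(tuple, W)) <= {(1.0, 0.0), (0.0, 1.0)}
    np.testing.assert_array_equal(W[:, 0], [1, 1, 1, 0, 0, 0])


@pytest.mark.parametrize("k,M", [(1, 2), (2, 4), (3, 3), (3, 7), (4, 6)])
def test_rows_sum_to_one(k, M, rng):
    x = rng.standard_normal(50)
    W = bspline_weights(x, k=k, M=M)
    assert W.min() >= 0
    np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-10)


def test_weights_match_cox_de_boor_recursion():
    # k=3, M=3: clamped knots [0,0,0,1,1,1], domain [0,1]; include the midpoint
    x = np.array([0.0, 0.25, 0.5, 0.8, 1.0])
    k, M = 3, 3
    W = bspline_weights(x, k=k, M=M)
    t = np.concatenate([np.zeros(k), np.full(k, float(M - k + 1))])
    pos = x / x.max() * (M - k + 1)
    pos = np.clip(pos, 0, np.nextafter(M - k + 1.0, 0))
    expected = np.array([[_cox_de_boor(p, t, k, i) for i in range(M)] for p in pos])
    np.testing.assert_allclose(W, expected, atol=1e-12)
    # midpoint of the quadratic basis: (1/4, 1/2, 1/4)
    np.testing.assert_allclose(W[2], [0.25, 0.5, 0.25], atol=1e-12)


def test_zero_range_input_raises():
    with pytest.raises(ValueError, match="zero-range"):
        bspline_weights(np.ones(5), k=3, M=4)


# ------------------------------------------------------------ bin rules

def test_bin_rule_contracts(rng):
    x12, y12 = rng.standard_normal(12), rng.standard_normal(12)
    x1k, y1k = rng.standard_normal(1000), rng.standard_normal(1000)
    assert select_bins(x12, y12, "fixed:10") == 10
    assert select_bins(x12, y12, 7) == 7
    assert select_bins(x1k, y1k, "sturges") >= select_bins(x12, y12, "sturges")
    assert select_bins(x12, y12, "sturges") == select_bins(y12, x12, "sturges")
    with pytest.raises(KeyError):
        select_bins(x12, y12, "no-such-rule")
    with pytest.raises(ValueError, match="M=2 < k=3"):
        select_bins(x12, y12, "fixed:2", k=3)


# ---------------------------------------------------- mutual information

def test_identical_binary_halves_give_log2():
    x = np.array([0.0, 0, 0, 1, 1, 1])
    cfg = MIEstimatorConfig(spline_order_k=1, bin_rule=2)
    res = mutual_information(x, x, cfg)
    assert res.mi == pytest.approx(np.log(2), abs=1e-12)


def test_matches_closed_form_discrete_mi():
    # joint table {(0,0):0.4, (0,1):0.1, (1,0):0.1, (1,1):0.4} over 10 samples
    x = np.array([0.0] * 5 + [1.0] * 5)
    y = np.array([0.0] * 4 + [1.0] + [0.0] + [1.0] * 4)
    probs = {(0, 0): 0.4, (0, 1): 0.1, (1, 0): 0.1, (1, 1): 0.4}
    closed = sum(p * np.log(p / 0.25) for p in probs.values())
    cfg = MIEstimatorConfig(spline_order_k=1, bin_rule=2)
    assert mutual_information(x, y, cfg).mi == pytest.approx(closed, abs=1e-9)
    assert closed == pytest.approx(0.1927, abs=5e-5)


def test_k1_equals_contingency_table_mi_on_bin_aligned_data(rng):
    """With order-1 splines the estimator must equal discrete MI of the
    contingency table, for any bin-aligned sample."""
    M = 4
    x = rng.integers(0, M, 60).astype(float)
    y = rng.integers(0, M, 60).astype(float)
    cfg = MIEstimatorConfig(spline_order_k=1, bin_rule=M)
    est = mutual_information(x, y, cfg).mi
    counts = np.zeros((M, M))
    for xi, yi in zip(x.astype(int), y.astype(int)):
        counts[xi, yi] += 1
    p = counts / counts.sum()
    px, py = p.sum(1), p.sum(0)
    mask = p > 0
    oracle = float(np.sum(p[mask] * np.log(p[mask] / np.outer(px, py)[mask])))
    assert est == pytest.approx(oracle, abs=1e-9)


def test_symmetry_and_nonnegativity(rng):
    x = rng.standard_normal(30)
    y = rng.standard_normal(30)
    cfg = MIEstimatorConfig()
    a = mutual_information(x, y, cfg)
    b = mutual_information(y, x, cfg)
    assert a.mi == pytest.approx(b.mi, abs=1e-12)
    assert a.M_used == b.M_used
    assert a.mi >= -1e-12


def test_independent_large_sample_mi_near_zero(rng):
    x = rng.standard_normal(10000)
    y = rng.standard_normal(10000)
    cfg = MIEstimatorConfig(spline_order_k=1, bin_rule=2)
    assert mutual_information(x, y, cfg).mi < 0.01


def test_length_mismatch_raises(rng):
    with pytest.raises(ValueError, match="same length"):
        mutual_information(rng.standard_normal(5), rng.standard_normal(6))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(8, 40))
def test_mi_nonnegative_property(seed, n):
    rng = np.random.default_rng(seed)
    x, y = rng.standard_normal(n), rng.standard_normal(n)
    assert mutual_information(x, y).mi >= -1e-12


# ------------------------------------------------- independence test

def test_strong_dependence_gives_zero_p(rng):
    x = rng.standard_normal(24)
    res = permutation_test_independence(x, x, MIEstimatorConfig(seed=0), pair=("a", "b"))
    assert res.p_value == 0.0


def test_permutation_p_is_count_ratio_and_seeded(rng):
    x, y = rng.standard_normal(12), rng.standard_normal(12)
    cfg = MIEstimatorConfig(seed=5)
    r1 = permutation_test_independence(x, y, cfg, pair=("m1", "m2"))
    r2 = permutation_test_independence(x, y, cfg, pair=("m1", "m2"))
    assert r1.p_value == r2.p_value
    assert 0 <= r1.p_value <= 1
    assert (r1.p_value * cfg.n_permutations_B) == pytest.approx(
        round(r1.p_value * cfg.n_permutations_B))
    # the smoothed convention shifts to (c+1)/(B+1)
    cfg2 = MIEstimatorConfig(seed=5, add_one_smoothing=True)
    r3 = permutation_test_independence(x, y, cfg2, pair=("m1", "m2"))
    assert r3.p_value == pytest.approx(
        (r1.p_value * cfg.n_permutations_B + 1) / (cfg.n_permutations_B + 1))


def test_pair_seed_makes_result_order_independent(rng):
    x, y = rng.standard_normal(12), rng.standard_normal(12)
    cfg = MIEstimatorConfig(seed=9)
    p_ab = permutation_test_independence(x, y, cfg, pair=("a", "b")).p_value
    # same pair written in the other order must use the same stream
    p_ba = permutation_test_independence(x, y, cfg, pair=("b", "a")).p_value
    assert p_ab == p_ba


# ------------------------------------------------- MI-difference test

def test_mi_difference_null_true_by_construction(rng):
    x = rng.standard_normal(12)
    y = 0.9 * x + 0.3 * rng.standard_normal(12)
    p = permutation_test_mi_difference(x, y, x, y, MIEstimatorConfig(seed=1),
                                       pair=("a", "b"))
    assert p >= 0.5  # observed statistic is 0; most null re-splits exceed it


def test_mi_difference_detects_lost_dependence():
    ps = []
    for seed in range(7):
        rng = np.random.default_rng(seed)
        x0 = rng.standard_normal(12)
        y0 = 0.95 * x0 + np.sqrt(1 - 0.95 ** 2) * rng.standard_normal(12)
        x4, y4 = rng.standard_normal(12), rng.standard_normal(12)
        ps.append(permutation_test_mi_difference(
            x0, y0, x4, y4, MIEstimatorConfig(seed=seed), pair=("a", "b")))
    assert np.median(ps) < 0.05


def test_mi_difference_seeded_determinism(rng):
    x0, y0 = rng.standard_normal(11), rng.standard_normal(11)
    x4, y4 = rng.standard_normal(12), rng.standard_normal(12)
    cfg = MIEstimatorConfig(seed=4)
    assert (permutation_test_mi_difference(x0, y0, x4, y4, cfg, pair=("a", "b"))
            == permutation_test_mi_difference(x0, y0, x4, y4, cfg, pair=("a", "b")))


def test_mi_difference_rejects_tiny_groups(rng):
    with pytest.raises(ValueError, match="at least 3"):
        permutation_test_mi_difference(
            rng.standard_normal(2), rng.standard_normal(2),
            rng.standard_normal(12), rng.standard_normal(12))
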