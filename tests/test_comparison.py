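"""Tests for chi-squared distances, rankings, the CvM test and Torgerson MDS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from etnet import (chi2_histogram_distance, compare_et_distributions,
                   cvm_two_sample, et_distribution, net_change_ranking,
                   torgerson_mds)
from etnet.comparison import et_distance_matrix, major_class_subset


# ------------------------------------------------------------ chi-squared

def test_chi2_identity_disjoint_and_hand_value():
    assert chi2_histogram_distance([0.5, 0.5], [0.5, 0.5]) == 0.0
    assert chi2_histogram_distance([1, 0], [0, 1]) == 1.0
    assert chi2_histogram_distance([0.5, 0.5], [1, 0]) == pytest.approx(1 / 3)


def test_chi2_normalizes_and_validates():
    # unnormalized inputs are scaled to sum 1 first
    assert chi2_histogram_distance([5, 5], [10, 0]) == pytest.approx(1 / 3)
    with pytest.raises(ValueError, match="same length"):
        chi2_histogram_distance([1, 0], [1, 0, 0])
    with pytest.raises(ValueError, match="nonnegative"):
        chi2_histogram_distance([1, -1], [1, 0])
    with pytest.raises(ValueError, match="all-zero"):
        chi2_histogram_distance([0, 0], [1, 0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 100), min_size=2, max_size=10),
       st.lists(st.floats(0, 100), min_size=2, max_size=10))
def test_chi2_symmetric_and_bounded(p, q):
    n = min(len(p), len(q))
    p, q = np.asarray(p[:n]) + 1e-3, np.asarray(q[:n]) + 1e-3
    d = chi2_histogram_distance(p, q)
    assert 0 <= d <= 1
    assert d == pytest.approx(chi2_histogram_distance(q, p), abs=1e-12)


# ---------------------------------------------------------------- ranking

def test_ranking_orders_by_net_gain_with_stable_ties():
    dists = {("A", "A"): {"AtoP": 5.0, "PtoA": 2.0},
             ("A", "C"): {"AtoP": 1.0, "PtoA": 1.0},
             ("C", "C"): {"AtoP": 0.0, "PtoA": 0.0}}
    rank = net_change_ranking(dists)
    assert list(rank["et"]) == ["A--A", "A--C", "C--C"]
    assert rank.loc[1, "net_change"] == 3.0
    swapped = {et: {"AtoP": h["PtoA"], "PtoA": h["AtoP"]}
               for et, h in dists.items()}
    rank_sw = net_change_ranking(swapped)
    assert list(rank_sw["net_change"]) == [-v for v in rank["net_change"][::-1]]


# ------------------------------------------------------------------- CvM

def _cvm_bruteforce(a, b):
    """Direct evaluation over the pooled empirical distribution functions."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    Fa = np.array([np.mean(a <= z) for z in pooled])
    Fb = np.array([np.mean(b <= z) for z in pooled])
    return n * m / (n + m) ** 2 * np.sum((Fa - Fb) ** 2)


def test_cvm_statistic_matches_bruteforce():
    res = cvm_two_sample([1, 1, 1, 1], [10, 10, 10, 10])
    assert res.statistic == pytest.approx(_cvm_bruteforce([1] * 4, [10] * 4), abs=1e-12)
    rng = np.random.default_rng(3)
    a, b = rng.standard_normal(13), rng.standard_normal(9) + 0.4
    res = cvm_two_sample(a, b)
    assert res.statistic == pytest.approx(_cvm_bruteforce(a, b), abs=1e-12)


def test_cvm_identical_samples_not_significant(rng):
    a = rng.standard_normal(20)
    res = cvm_two_sample(a, a.copy())
    assert res.p_value > 0.1


def test_cvm_invariant_to_order_preserving_relabeling(rng):
    a = rng.integers(1, 6, 30).astype(float)
    b = rng.integers(1, 6, 25).astype(float)
    res1 = cvm_two_sample(a, b)
    relabel = {1: 10, 2: 20, 3: 22, 4: 40, 5: 100}
    res2 = cvm_two_sample([relabel[v] for v in a], [relabel[v] for v in b])
    assert res1.statistic == pytest.approx(res2.statistic, abs=1e-12)


def test_cvm_permutation_p_roughly_calibrated():
    rng = np.random.default_rng(8)
    ps = []
    for i in range(100):
        a = rng.choice(5, 25).astype(float)
        b = rng.choice(5, 25).astype(float)
        ps.append(cvm_two_sample(a, b, method="permutation",
                                 n_permutations=199, seed=i).p_value)
    assert 0.01 <= np.mean(np.asarray(ps) < 0.05) <= 0.12


def test_cvm_rejects_empty_sample():
    with pytest.raises(ValueError, match="nonempty"):
        cvm_two_sample([], [1.0])


def test_compare_et_distributions_separation_and_cap(abc_catalog):
    anno = {f"a{i}": frozenset({"A"}) for i in range(8)}
    anno.update({f"c{i}": frozenset({"C"}) for i in range(8)})
    edges_a = [(f"a{i}", f"a{j}") for i in range(8) for j in range(i + 1, 8)]
    edges_c = [(f"c{i}", f"c{j}") for i in range(8) for j in range(i + 1, 8)]
    da = et_distribution(edges_a, anno, abc_catalog)
    dc = et_distribution(edges_c, anno, abc_catalog)
    res = compare_et_distributions(da, dc, abc_catalog, bonferroni=6)
    assert res.p_value < 0.05  # disjoint fingerprints stay significant after x6
    same = compare_et_distributions(da, da, abc_catalog, bonferroni=6)
    assert same.p_value == 1.0  # cap at 1


# ------------------------------------------------------------------- MDS

def test_mds_two_points_recover_their_distance():
    D = np.array([[0.0, 3.0], [3.0, 0.0]])
    coords = torgerson_mds(D, dim=1)
    assert abs(coords.iloc[0, 0] - coords.iloc[1, 0]) == pytest.approx(3.0)


def test_mds_recovers_planar_configuration(rng):
    pts = rng.standard_normal((4, 2))
    D = squareform(pdist(pts))
    coords = torgerson_mds(pd.DataFrame(D), dim=2).to_numpy()
    D_hat = squareform(pdist(coords))
    np.testing.assert_allclose(D_hat, D, atol=1e-9)


def test_mds_zero_matrix_gives_origin():
    coords = torgerson_mds(np.zeros((3, 3)), dim=2)
    assert np.allclose(coords, 0)
    assert coords.shape == (3, 2)


def test_mds_truncates_nonexistent_dimensions():
    # three collinear points span one dimension only
    D = np.abs(np.subtract.outer([0.0, 1.0, 4.0], [0.0, 1.0, 4.0]))
    coords = torgerson_mds(D, dim=2)
    assert coords.shape[1] == 1


def test_mds_agrees_with_pcoa_reference():
    """Cross-check against an independent principal-coordinates solver."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(5)
    pts = rng.standard_normal((6, 3))
    D = squareform(pdist(pts))
    ours = torgerson_mds(pd.DataFrame(D), dim=3).to_numpy()
    ref = skbio.stats.ordination.pcoa(D, number_of_dimensions=3).samples.to_numpy()
    np.testing.assert_allclose(np.abs(ours), np.abs(ref), atol=1e-8)


def test_mds_rejects_asymmetric_input():
    with pytest.raises(ValueError, match="symmetric"):
        torgerson_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_distance_matrix_drops_empty_ets_and_is_symmetric(catalog):
    subset = major_class_subset(catalog)
    assert len(subset) == 15
    rng = np.random.default_rng(0)
    hists = {et: rng.random(4) for et in subset}
    hists[subset[0]] = np.zeros(4)  # undefined: dropped
    D = et_distance_matrix(hists, subset)
    assert D.shape == (14, 14)
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0)
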