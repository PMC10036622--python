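"""Network-state comparison: chi-squared histogram distances, net-change
rankings, the two-sample Cramér–von Mises test on ET distributions, and
classical (Torgerson) multidimensional scaling.

The chi-squared histogram distance between two normalized histograms,

    chi2(P, Q) = 1/2 * sum_i (P_i - Q_i)^2 / (P_i + Q_i),

is bounded in [0, 1]: 0 iff the histograms coincide, 1 iff their supports
are disjoint.  It is not a metric (the triangle inequality can fail), which
is why the embedding step uses Torgerson scaling of the squared distances
rather than assuming Euclidean structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .edge_typing import ETCatalog, ETDistribution

__all__ = [
    "chi2_histogram_distance",
    "net_change_ranking",
    "cvm_two_sample",
    "CvMResult",
    "compare_et_distributions",
    "et_distance_matrix",
    "torgerson_mds",
    "major_class_subset",
]

# the five major metabolism classes used for the focused 15-ET comparisons
MAJOR_CLASSES = ("Amino acid", "Carbohydrate", "Energy", "Lipid", "Nucleotide")


def major_class_subset(catalog: ETCatalog,
                       classes: Sequence[str] = MAJOR_CLASSES) -> list[tuple[str, str]]:
    """The ETs whose both endpoint labels are in ``classes`` (15 for the
    default five major classes)."""
    want = set(classes)
    return [et for et in catalog.pairs if et[0] in want and et[1] in want]


def chi2_histogram_distance(P: np.ndarray, Q: np.ndarray) -> float:
    """Chi-squared histogram distance between two histograms.

    Inputs are normalized to sum 1 first; bins empty in both histograms
    contribute 0.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("histograms must have the same length")
    if np.any(P < 0) or np.any(Q < 0):
        raise ValueError("histogram entries must be nonnegative")
    if P.sum() == 0 or Q.sum() == 0:
        raise ValueError("all-zero histogram")
    P = P / P.sum()
    Q = Q / Q.sum()
    denom = P + Q
    mask = denom > 0
    return float(0.5 * np.sum((P[mask] - Q[mask]) ** 2 / denom[mask]))


def net_change_ranking(
    resp_dists: Mapping[tuple[str, str], Mapping[str, float]],
) -> pd.DataFrame:
    """Rank ETs by net edge gain, AtoP weight minus PtoA weight, descending.

    Positive values mean the later condition gained edges of that ET.  Ties
    break lexicographically by ET label pair, so the ranking is stable.
    """
    rows = []
    for et, hist in resp_dists.items():
        gain = hist.get("AtoP", 0.0)
        loss = hist.get("PtoA", 0.0)
        rows.append((f"{et[0]}--{et[1]}", gain, loss, gain - loss))
    df = pd.DataFrame(rows, columns=["et", "AtoP", "PtoA", "net_change"])
    df = df.sort_values(["net_change", "et"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df.index = pd.RangeIndex(1, len(df) + 1, name="rank")
    return df


@dataclass(frozen=True)
class CvMResult:
    statistic: float  # the two-sample Cramér–von Mises T statistic
    p_value: float
    correction: int = 1


def cvm_two_sample(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    method: str = "asymptotic",
    n_permutations: int = 999,
    seed: int = 0,
) -> CvMResult:
    """Two-sample Cramér–von Mises test.

    H0: the two samples are drawn from the same distribution.  The
    statistic integrates the squared difference of the two empirical
    distribution functions over the pooled sample; ties are handled by the
    midrank convention.  ``method`` selects the asymptotic p-value
    (default), the small-sample ``"exact"`` distribution, or a
    ``"permutation"`` p-value with the given replicate count.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if method == "permutation":
        rng = np.random.default_rng(seed)
        res = stats.cramervonmises_2samp(
            a, b, method="asymptotic")
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            null = stats.cramervonmises_2samp(
                pooled[:len(a)], pooled[len(a):], method="asymptotic").statistic
            if null >= res.statistic:
                count += 1
        return CvMResult(float(res.statistic), (count + 1) / (n_permutations + 1))
    res = stats.cramervonmises_2samp(a, b, method=method)
    return CvMResult(float(res.statistic), float(min(1.0, res.pvalue)))


def expand_to_ordinal_samples(
    dist: ETDistribution,
    catalog: ETCatalog,
    resolution: float = 1.0,
) -> np.ndarray:
    """Turn a weighted ET distribution into replicated ordinal observations.

    ETs are ordered by catalog index (1..t); each ET contributes
    round(weight / resolution) copies of its ordinal.  This is how a
    weighted categorical fingerprint is fed to a rank-based two-sample
    test.
    """
    out = []
    for idx, et in enumerate(catalog.pairs, start=1):
        n = int(round(dist.weights.get(et, 0.0) / resolution))
        out.extend([idx] * n)
    return np.asarray(out, dtype=float)


def compare_et_distributions(
    dist_a: ETDistribution,
    dist_b: ETDistribution,
    catalog: ETCatalog,
    bonferroni: int = 1,
    resolution: float = 1.0,
    method: str = "asymptotic",
) -> CvMResult:
    """CvM test of whether two ET fingerprints come from one distribution.

    Weighted counts are expanded to ordinal samples at the given weight
    resolution; the caller supplies the Bonferroni family size (6 for all
    pairwise comparisons of four conditions within a layer).
    """
    sa = expand_to_ordinal_samples(dist_a, catalog, resolution)
    sb = expand_to_ordinal_samples(dist_b, catalog, resolution)
    if len(sa) == 0 or len(sb) == 0:
        raise ValueError("zero-total ET distribution")
    base = cvm_two_sample(sa, sb, method=method)
    return CvMResult(base.statistic, min(1.0, base.p_value * bonferroni), bonferroni)


def et_distance_matrix(
    histograms: Mapping[tuple[str, str], Sequence[float]],
    ets: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Symmetric chi-squared distance matrix between per-ET histograms.

    ETs whose histogram is all-zero are dropped (distance undefined); the
    returned frame records which ETs survived in its index.
    """
    kept = [et for et in ets if np.asarray(histograms[et], float).sum() > 0]
    names = [f"{a}--{b}" for a, b in kept]
    n = len(kept)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = chi2_histogram_distance(np.asarray(histograms[kept[i]], float),
                                        np.asarray(histograms[kept[j]], float))
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=names, columns=names)


def torgerson_mds(D: pd.DataFrame | np.ndarray, dim: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of a distance matrix.

    The squared distances are double-centered, B = -1/2 J D^2 J, and the
    coordinates are the top eigenvectors scaled by the square roots of
    their (nonnegative) eigenvalues — the closed-form minimizer of the
    strain objective.  Negative eigenvalues (non-Euclidean input) are
    truncated; if fewer than ``dim`` positive eigenvalues exist, fewer
    columns are returned.  For sign reproducibility each coordinate's
    largest-magnitude loading is made positive.
    """
    if isinstance(D, pd.DataFrame):
        labels = list(D.index)
        M = D.to_numpy(dtype=float)
    else:
        M = np.asarray(D, dtype=float)
        labels = list(range(M.shape[0]))
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(M), 0, atol=1e-12):
        raise ValueError("distance matrix must have zero diagonal")
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > 1e-12 * max(1.0, abs(eigval[0]))
    n_keep = min(dim, int(positive.sum()))
    if n_keep == 0:
        return pd.DataFrame(np.zeros((n, dim)), index=labels,
                            columns=[f"dim{m + 1}" for m in range(dim)])
    coords = eigvec[:, :n_keep] * np.sqrt(eigval[:n_keep])
    for m in range(n_keep):
        j = np.argmax(np.abs(coords[:, m]))
        if coords[j, m] < 0:
            coords[:, m] = -coords[:, m]
    return pd.DataFrame(coords, index=labels,
                        columns=[f"dim{m + 1}" for m in range(n_keep)])
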