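"""Pairwise mutual-information estimation with B-spline density estimation.

The joint density of a molecule pair is estimated by fractional binning:
each observation is spread over ``M`` bins with the weights of the order-``k``
B-spline basis evaluated at its (range-mapped) position, so the joint
probability table is the sample mean of the outer products of the two weight
rows.  Order ``k = 1`` reduces to an ordinary 2-D histogram.  Statistical
independence is assessed with a permutation test (the first variable is
permuted, the second held fixed), and a second permutation test asks whether
the MI of a pair differs between two conditions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "MIEstimatorConfig",
    "PairwiseMIResult",
    "standardize",
    "bspline_weights",
    "select_bins",
    "mutual_information",
    "permutation_test_independence",
    "permutation_test_mi_difference",
    "register_bin_rule",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class MIEstimatorConfig:
    """Settings shared by every pairwise MI computation.

    Parameters
    ----------
    spline_order_k : B-spline order (1 = piecewise constant, i.e. plain
        histogram binning; 3 = quadratic splines, the default).
    bin_rule : name of a registered rule mapping a sample pair to the bin
        count ``M`` ("sturges", "sqrt", or "fixed:<M>"), or an integer for a
        fixed ``M``.
    n_permutations_B : size of the empirical null distribution.
    seed : root seed; per-pair streams are derived from it and the pair's
        molecule IDs so results never depend on evaluation order.
    add_one_smoothing : if True use the (c+1)/(B+1) p-value convention
        instead of the plain count ratio c/B (which can be exactly 0).
    """

    spline_order_k: int = 3
    bin_rule: Union[str, int] = "sturges"
    n_permutations_B: int = 500
    seed: int = 0
    add_one_smoothing: bool = False

    def __post_init__(self) -> None:
        if self.spline_order_k < 1:
            raise ValueError("spline order k must be >= 1")
        if self.n_permutations_B < 1:
            raise ValueError("number of permutations B must be >= 1")


@dataclass(frozen=True)
class PairwiseMIResult:
    pair: tuple[str, str]
    mi: float
    p_value: float | None
    M_used: int


# ---------------------------------------------------------------------------
# standardization

def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Standardize each molecule row to mean 0 and (ddof=1) sd 1.

    Returns the standardized matrix and the list of molecule IDs whose row
    was constant (zero variance); those rows are excluded from the result
    rather than silently kept, and callers must report them as untested.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite values")
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    excluded = list(matrix.index[constant])
    kept = values[~constant]
    kept = (kept - kept.mean(axis=1, keepdims=True)) / sd[~constant, None]
    return pd.DataFrame(kept, index=matrix.index[~constant], columns=matrix.columns), excluded


# ---------------------------------------------------------------------------
# B-spline fractional binning

def _knot_vector(k: int, M: int) -> np.ndarray:
    # clamped uniform knots: domain [0, M - k + 1], M basis functions of order k
    interior = np.arange(1, M - k + 1, dtype=float)
    return np.concatenate([np.zeros(k), interior, np.full(k, M - k + 1.0)])


def bspline_weights(x: np.ndarray, k: int, M: int) -> np.ndarray:
    """Evaluate the M order-k B-spline basis functions at each sample.

    The sample range [min(x), max(x)] is mapped linearly onto the spline
    domain.  Rows sum to 1 (partition of unity).  A zero-range input has no
    defined mapping and raises.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("x contains non-finite values")
    if M < k:
        raise ValueError(f"need M >= k, got M={M}, k={k}")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("zero-range input: all values equal")
    t = _knot_vector(k, M)
    pos = (x - lo) / (hi - lo) * (M - k + 1)
    # keep the right boundary inside the half-open support of the last basis
    pos = np.clip(pos, 0.0, np.nextafter(M - k + 1.0, 0.0))
    W = BSpline.design_matrix(pos, t, k - 1).toarray()
    return W


# ---------------------------------------------------------------------------
# bin-count rules

def _sturges(x: np.ndarray, y: np.ndarray, k: int) -> int:
    n = len(x)
    return int(np.clip(int(np.log2(n)) + 1, k, max(k, n // 2)))


def _sqrt_rule(x: np.ndarray, y: np.ndarray, k: int) -> int:
    n = len(x)
    return int(np.clip(round(np.sqrt(n)), k, max(k, n // 2)))


_BIN_RULES: dict[str, Callable[[np.ndarray, np.ndarray, int], int]] = {
    "sturges": _sturges,
    "sqrt": _sqrt_rule,
}


def register_bin_rule(name: str, fn: Callable[[np.ndarray, np.ndarray, int], int]) -> None:
    _BIN_RULES[name] = fn


def select_bins(x: np.ndarray, y: np.ndarray, rule: Union[str, int], k: int = 3) -> int:
    """Resolve the bin count M for a variable pair.

    Rules are symmetric in (x, y) and deterministic.  ``"fixed:M"`` or an
    integer gives a constant M; named rules depend on the sample size only.
    """
    if isinstance(rule, (int, np.integer)):
        M = int(rule)
    elif rule.startswith("fixed:"):
        M = int(rule.split(":", 1)[1])
    elif rule in _BIN_RULES:
        M = _BIN_RULES[rule](np.asarray(x), np.asarray(y), k)
    else:
        raise KeyError(f"unknown bin rule {rule!r}")
    if M < k:
        raise ValueError(f"bin rule produced M={M} < k={k}")
    return M


# ---------------------------------------------------------------------------
# mutual information

def _mi_from_joint(joint: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    ref = np.outer(px, py)
    mask = joint > 0
    return float(np.sum(joint[mask] * (np.log(joint[mask]) - np.log(ref[mask]))))


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    cfg: MIEstimatorConfig = MIEstimatorConfig(),
    *,
    M: int | None = None,
) -> PairwiseMIResult:
    """Plug-in MI estimate (nats) from the B-spline joint density.

    I = sum_ij p(i,j) log[ p(i,j) / (p_x(i) p_y(j)) ], where p(i,j) is the
    sample mean of the outer product of the two basis-weight rows.  Cells
    with p(i,j) = 0 contribute 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    k = cfg.spline_order_k
    if M is None:
        M = select_bins(x, y, cfg.bin_rule, k)
    Wx = bspline_weights(x, k, M)
    Wy = bspline_weights(y, k, M)
    n = len(x)
    joint = Wx.T @ Wy / n
    px = Wx.mean(axis=0)
    py = Wy.mean(axis=0)
    mi = _mi_from_joint(joint, px, py)
    return PairwiseMIResult(pair=("x", "y"), mi=mi, p_value=None, M_used=M)


def _pair_rng(cfg: MIEstimatorConfig, pair: tuple[str, str] | None) -> np.random.Generator:
    if pair is None:
        return np.random.default_rng(cfg.seed)
    a, b = sorted(str(p) for p in pair)
    digest = hashlib.blake2b(f"{a}\x00{b}".encode(), digest_size=8).digest()
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, int.from_bytes(digest, "big")]))


def _null_mis(Wx: np.ndarray, Wy: np.ndarray, rng: np.random.Generator, B: int) -> np.ndarray:
    """MI of B row-permuted copies of Wx against fixed Wy, vectorized.

    Permuting samples of x permutes rows of its weight matrix; the marginals
    are permutation-invariant, so only the joint table changes.
    """
    n, M = Wx.shape
    idx = np.argsort(rng.random((B, n)), axis=1)
    joint = np.einsum("bnm,nk->bmk", Wx[idx], Wy) / n
    px = Wx.mean(axis=0)
    py = Wy.mean(axis=0)
    log_ref = np.log(np.outer(px, py))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * (np.log(joint) - log_ref)
    terms[joint <= 0] = 0.0
    return terms.sum(axis=(1, 2))


def _p_from_counts(count: int, B: int, add_one: bool) -> float:
    if add_one:
        return (count + 1) / (B + 1)
    return count / B


def permutation_test_independence(
    x: np.ndarray,
    y: np.ndarray,
    cfg: MIEstimatorConfig = MIEstimatorConfig(),
    *,
    pair: tuple[str, str] | None = None,
) -> PairwiseMIResult:
    """Permutation test of H0: I(X;Y) = 0.

    The null distribution is the MI recomputed after B independent uniform
    permutations of x with y fixed; p is the fraction of null samples
    strictly larger than the observed MI.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    k = cfg.spline_order_k
    M = select_bins(x, y, cfg.bin_rule, k)
    Wx = bspline_weights(x, k, M)
    Wy = bspline_weights(y, k, M)
    n = len(x)
    joint = Wx.T @ Wy / n
    px, py = Wx.mean(axis=0), Wy.mean(axis=0)
    observed = _mi_from_joint(joint, px, py)
    rng = _pair_rng(cfg, pair)
    null = _null_mis(Wx, Wy, rng, cfg.n_permutations_B)
    p = _p_from_counts(int(np.sum(null > observed)), cfg.n_permutations_B, cfg.add_one_smoothing)
    return PairwiseMIResult(pair=pair if pair is not None else ("x", "y"),
                            mi=observed, p_value=p, M_used=M)


def permutation_test_mi_difference(
    x0: np.ndarray,
    y0: np.ndarray,
    x4: np.ndarray,
    y4: np.ndarray,
    cfg: MIEstimatorConfig = MIEstimatorConfig(),
    *,
    pair: tuple[str, str] | None = None,
) -> float:
    """Permutation test of H0: the pair's MI is equal in the two conditions.

    The statistic is |I_0 - I_4|.  Under the null the (x, y) sample pairs of
    both conditions are exchangeable, so the pooled pairs are randomly
    re-split into groups of the original sizes B times; within-sample x-y
    pairing is preserved.
    """
    x0, y0 = np.asarray(x0, float), np.asarray(y0, float)
    x4, y4 = np.asarray(x4, float), np.asarray(y4, float)
    n0, n4 = len(x0), len(x4)
    if n0 < 3 or n4 < 3:
        raise ValueError("need at least 3 samples in each condition")
    if x0.shape != y0.shape or x4.shape != y4.shape:
        raise ValueError("x and y must be paired within each condition")
    k = cfg.spline_order_k
    M0 = select_bins(x0, y0, cfg.bin_rule, k)
    M4 = select_bins(x4, y4, cfg.bin_rule, k)

    def _mi(x: np.ndarray, y: np.ndarray, M: int) -> float:
        Wx = bspline_weights(x, k, M)
        Wy = bspline_weights(y, k, M)
        joint = Wx.T @ Wy / len(x)
        return _mi_from_joint(joint, Wx.mean(axis=0), Wy.mean(axis=0))

    observed = abs(_mi(x0, y0, M0) - _mi(x4, y4, M4))
    pool_x = np.concatenate([x0, x4])
    pool_y = np.concatenate([y0, y4])
    rng = _pair_rng(cfg, pair)
    B = cfg.n_permutations_B
    count = 0
    for _ in range(B):
        perm = rng.permutation(n0 + n4)
        a, b = perm[:n0], perm[n0:]
        stat = abs(_mi(pool_x[a], pool_y[a], M0) - _mi(pool_x[b], pool_y[b], M4))
        if stat > observed:
            count += 1
    return _p_from_counts(count, B, cfg.add_one_smoothing)
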