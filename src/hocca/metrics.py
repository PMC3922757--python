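"""Evaluation metrics: Amari index, Hoyer sparsity, histogram mutual
information with Miller-Madow correction, parametric bivariate-t mutual
information, and multi-information reduction.

All mutual-information quantities are reported in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.special import gammaln, psi

from .model import SourcePairParams, pair_logdensity

__all__ = [
    "MIEstimate",
    "amari_index",
    "sparsity_index",
    "mi_histogram",
    "gaussian_mi",
    "shape_mi",
    "mi_parametric",
    "mi_parametric_quadrature",
    "gaussian_equivalent_rho",
    "multiinfo_reduction",
    "GAUSSIAN_SPARSITY",
]

LN2 = np.log(2.0)

#: Large-sample Hoyer sparsity of an iid Gaussian sequence, 1 - sqrt(2/pi).
GAUSSIAN_SPARSITY = 1.0 - np.sqrt(2.0 / np.pi)


@dataclass(frozen=True)
class MIEstimate:
    """A histogram mutual-information estimate (bits)."""

    value: float
    n_bins: int
    n_samples: int
    estimator: str = "miller_madow"


def _sinkhorn_balance(Q: np.ndarray, n_iter: int = 200, tol: float = 1e-12) -> np.ndarray:
    """Alternately normalize rows and columns of a nonnegative matrix to
    unit sum.  For matrices with total support this converges to the
    unique doubly stochastic scaling D1 Q D2, which makes any statistic
    of the balanced matrix exactly invariant to row/column rescaling."""
    B = Q.copy()
    for _ in range(n_iter):
        B /= B.sum(axis=1, keepdims=True)
        B /= B.sum(axis=0, keepdims=True)
        if np.abs(B.sum(axis=1) - 1.0).max() < tol:
            break
    return B


def amari_index(P: np.ndarray) -> float:
    """Permutation- and scale-invariant distance of ``P`` from the set of
    scaled permutation matrices.

    The absolute matrix is first Sinkhorn-balanced (rows/columns scaled
    to unit sums), then the classical Amari performance sums are applied
    and normalized by ``2 K (K - 1)``.  The index is zero iff ``P`` is a
    scaled permutation matrix, invariant to row/column rescaling by
    nonzero constants and to row/column permutations, and of order one
    for a random dense matrix.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be a square matrix")
    K = P.shape[0]
    if K < 2:
        raise ValueError("Amari index requires K >= 2")
    Q = np.abs(P)
    if np.any(Q.sum(axis=0) == 0) or np.any(Q.sum(axis=1) == 0):
        raise ValueError("P has an all-zero row or column")
    B = _sinkhorn_balance(Q)
    row = (B.sum(axis=1) / B.max(axis=1) - 1.0).sum()
    col = (B.sum(axis=0) / B.max(axis=0) - 1.0).sum()
    return float((row + col) / (2.0 * K * (K - 1)))


def sparsity_index(samples: np.ndarray) -> float:
    """Hoyer-type sparsity of a zero-mean sample sequence, in [0, 1].

    ``(sqrt(T) - ||s||_1 / ||s||_2) / (sqrt(T) - 1)``; approximately
    0.202 for Gaussian samples and larger for sparser (heavier-tailed,
    more peaked) distributions.  The mean is removed before evaluation.
    """
    s = np.asarray(samples, dtype=float).ravel()
    T = s.size
    if T < 2:
        raise ValueError("need at least two samples")
    s = s - s.mean()
    l2 = np.sqrt((s * s).sum())
    if l2 == 0:
        raise ValueError("all-zero input: sparsity undefined")
    ratio = np.abs(s).sum() / l2
    return float((np.sqrt(T) - ratio) / (np.sqrt(T) - 1.0))


def _hist_entropy_bits(counts: np.ndarray, n: int) -> float:
    """Plug-in entropy (bits) of histogram counts with Miller-Madow
    bias correction ``(m - 1) / (2 n ln 2)``."""
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum() + (p.size - 1) / (2.0 * n * LN2))


def mi_histogram(x, y, n_bins: int = 1000) -> MIEstimate:
    """Nonparametric mutual information between two sample sequences.

    The marginals are rank-transformed to uniform, a joint histogram on
    an ``n_bins x n_bins`` grid is formed, and the plug-in MI is
    Miller-Madow corrected (each entropy corrected by ``(m - 1)/(2T)``
    nats, ``m`` the number of occupied bins).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = x.size
    rx = (stats.rankdata(x, method="ordinal") - 0.5) / n
    ry = (stats.rankdata(y, method="ordinal") - 0.5) / n
    H, _, _ = np.histogram2d(rx, ry, bins=n_bins, range=[[0, 1], [0, 1]])
    hx = _hist_entropy_bits(H.sum(axis=1), n)
    hy = _hist_entropy_bits(H.sum(axis=0), n)
    hxy = _hist_entropy_bits(H.ravel(), n)
    return MIEstimate(value=hx + hy - hxy, n_bins=int(n_bins), n_samples=n)


def gaussian_mi(rho: float) -> float:
    """MI (bits) of a Gaussian pair with correlation ``rho``."""
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    return float(-0.5 * np.log2(1.0 - rho * rho))


def shape_mi(nu: float) -> float:
    """Non-Gaussian part c(nu) of the bivariate-t mutual information (bits).

    c(nu) is the MI of the unit-variance bivariate Student-t at rho = 0:
    ``c = 2 h1(nu) - h2(nu)`` with the univariate/bivariate t entropies,
    which reduces to the digamma expression below.  It is positive,
    decreasing in nu, and vanishes in the Gaussian limit.
    """
    nu = float(nu)
    if np.isinf(nu):
        return 0.0
    if nu <= 2.0:
        raise ValueError("nu must be > 2 under the unit-variance parameterization")
    nats = (
        gammaln((nu + 2) / 2)
        + gammaln(nu / 2)
        - 2.0 * gammaln((nu + 1) / 2)
        + (nu + 1) * psi((nu + 1) / 2)
        - (nu + 2) / 2 * psi((nu + 2) / 2)
        - nu / 2 * psi(nu / 2)
    )
    return float(nats / LN2)


def mi_parametric(params: SourcePairParams) -> float:
    """Parametric MI (bits) of a coupled pair: ``c(nu) + gaussian_mi(rho)``.

    The shape and correlation parameters contribute separately; the
    rho-part equals the Gaussian MI exactly, and c(nu) -> 0 as nu grows.
    """
    c = 0.0 if params.gaussian else shape_mi(params.nu)
    return c + gaussian_mi(params.rho)


def mi_parametric_quadrature(params: SourcePairParams) -> float:
    """MI (bits) of the coupled-pair density by 2-D numerical quadrature.

    Integrates ``p(s1, s2) * log2(p(s1, s2) / (p1(s1) p1(s2)))`` over the
    plane using the model log-density and the closed-form univariate-t
    marginal.  Serves as the independent oracle for :func:`mi_parametric`.
    """
    if params.gaussian:
        return gaussian_mi(params.rho)
    nu = params.nu

    def logp1(v):
        return (
            -(nu + 1) / 2 * np.log1p(v * v / (nu - 2))
            + gammaln((nu + 1) / 2)
            - gammaln(nu / 2)
            - 0.5 * np.log((nu - 2) * np.pi)
        )

    def integrand(s2, s1):
        lp = pair_logdensity(np.array([s1, s2]), params)
        return np.exp(lp) * (lp - logp1(s1) - logp1(s2)) / LN2

    val, _ = integrate.dblquad(integrand, -np.inf, np.inf, -np.inf, np.inf)
    return float(val)


def gaussian_equivalent_rho(mi_bits: float) -> float:
    """Correlation of a Gaussian pair whose MI equals ``mi_bits``."""
    if mi_bits < 0:
        raise ValueError("mutual information must be nonnegative")
    return float(np.sqrt(1.0 - 2.0 ** (-2.0 * mi_bits)))


def _marginal_entropy_bits(v: np.ndarray, n_bins: int | None) -> float:
    """Differential entropy (bits) of one coordinate by binned plug-in
    with Miller-Madow correction; Scott's-rule bin width by default."""
    v = np.asarray(v, dtype=float)
    n = v.size
    if n_bins is None:
        width = 3.49 * v.std() * n ** (-1.0 / 3.0)
        n_bins = max(int(np.ceil((v.max() - v.min()) / width)), 2)
    counts, edges = np.histogram(v, bins=n_bins)
    return _hist_entropy_bits(counts, n) + np.log2(edges[1] - edges[0])


def multiinfo_reduction(before: np.ndarray, after: np.ndarray, n_bins: int | None = None) -> float:
    """Reduction in multi-information (bits per dimension) achieved by an
    orthogonal recombination of coordinates.

    Because orthogonal maps preserve joint entropy, the reduction in
    total dependency equals the drop in the sum of marginal entropies:
    ``(sum H_i(before) - sum H_i(after)) / d``.  Raises if ``after`` is
    not (to sampling tolerance) an orthogonal transform of ``before``.
    """
    X = np.asarray(before, dtype=float)
    Z = np.asarray(after, dtype=float)
    if X.shape != Z.shape:
        raise ValueError("before and after must have the same shape")
    if X is not Z and not np.array_equal(X, Z):
        R, *_ = np.linalg.lstsq(X, Z, rcond=None)
        if not np.allclose(R.T @ R, np.eye(R.shape[1]), atol=0.05):
            raise ValueError("after is not an orthogonal transform of before")
    d = X.shape[1]
    h_before = sum(_marginal_entropy_bits(X[:, j], n_bins) for j in range(d))
    h_after = sum(_marginal_entropy_bits(Z[:, j], n_bins) for j in range(d))
    return float((h_before - h_after) / d)
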