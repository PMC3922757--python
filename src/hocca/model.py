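"""Coupled-sources generative model.

Each coupled pair of canonical coordinates (one per data set) is a
bivariate scale mixture of Gaussians: a correlated Gaussian pair with
correlation coefficient ``rho`` is multiplied by the square root of a
shared inverse-Gamma variance variable governed by the shape parameter
``nu``.  The resulting pair follows a unit-variance bivariate Student-t
distribution: ``rho`` carries the linear correlation across the two data
sets while ``nu`` controls tail heaviness and hence the strength of the
variance (energy) coupling.  Values of ``nu`` close to two mean strongly
non-Gaussian, sparse coordinates; large ``nu`` recovers the Gaussian /
classical-CCA regime.

Whitened observations are superpositions of orthonormal features driven
by these sources, independently across pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "NU_MIN",
    "SourcePairParams",
    "CoupledSourceSample",
    "CoupledBasis",
    "CoupledDataset",
    "precision_matrix",
    "g_nonlinearity",
    "pair_logdensity",
    "sample_coupled_sources",
    "generate_coupled_data",
]

#: Lower bound for the shape parameter under the unit-variance
#: parameterization (the inverse-Gamma scale (nu - 2) / 2 must be positive).
NU_MIN = 2.01


@dataclass(frozen=True)
class SourcePairParams:
    """Parameters of one coupled source pair.

    Parameters
    ----------
    rho : float
        Linear correlation coefficient between the two coordinates,
        in the open interval (-1, 1).
    nu : float or None
        Shape parameter of the bivariate Student-t (> 2 under the
        unit-variance parameterization).  Values in (2, NU_MIN) are
        clamped up to ``NU_MIN``.  ``None`` or ``inf`` denotes the
        Gaussian limit (used for CCA-derived pairs).
    """

    rho: float
    nu: float | None = None

    def __post_init__(self):
        rho = float(self.rho)
        if not np.isfinite(rho) or abs(rho) >= 1.0:
            raise ValueError(f"rho must be finite with |rho| < 1, got {self.rho}")
        object.__setattr__(self, "rho", rho)
        if self.nu is None or np.isinf(self.nu):
            object.__setattr__(self, "nu", None)
            return
        nu = float(self.nu)
        if not np.isfinite(nu) or nu <= 2.0:
            raise ValueError(f"nu must be > 2 (or None for the Gaussian limit), got {self.nu}")
        object.__setattr__(self, "nu", max(nu, NU_MIN))

    @property
    def gaussian(self) -> bool:
        return self.nu is None


@dataclass(frozen=True)
class CoupledSourceSample:
    """A Monte-Carlo draw of one coupled source pair."""

    s_x: np.ndarray
    s_y: np.ndarray
    params: SourcePairParams
    seed: int | None = None

    def __post_init__(self):
        if len(self.s_x) != len(self.s_y):
            raise ValueError("s_x and s_y must have equal length")


def _check_orthonormal(W: np.ndarray, name: str, tol: float = 1e-8) -> None:
    K = W.shape[1]
    if K and not np.allclose(W.T @ W, np.eye(K), atol=tol):
        raise ValueError(f"{name} columns are not orthonormal (tolerance {tol})")


@dataclass
class CoupledBasis:
    """Two column-paired orthonormal feature matrices with per-pair parameters.

    ``W_x`` is ``(d_x, K)``, ``W_y`` is ``(d_y, K)``; column ``i`` of each
    forms coupled pair ``i`` with parameters ``pairs[i]``.
    """

    W_x: np.ndarray
    W_y: np.ndarray
    pairs: Sequence[SourcePairParams]
    pair_order: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.W_x = np.asarray(self.W_x, dtype=float)
        self.W_y = np.asarray(self.W_y, dtype=float)
        if self.W_x.shape[1] != self.W_y.shape[1]:
            raise ValueError("W_x and W_y must have the same number of columns")
        if self.W_x.shape[1] != len(self.pairs):
            raise ValueError("one SourcePairParams required per column pair")
        if self.n_pairs > min(self.W_x.shape[0], self.W_y.shape[0]):
            raise ValueError("more pairs than min(d_x, d_y)")
        _check_orthonormal(self.W_x, "W_x")
        _check_orthonormal(self.W_y, "W_y")

    @property
    def n_pairs(self) -> int:
        return self.W_x.shape[1]

    @property
    def rhos(self) -> np.ndarray:
        return np.array([p.rho for p in self.pairs])

    @property
    def nus(self) -> np.ndarray:
        return np.array([np.inf if p.nu is None else p.nu for p in self.pairs])


@dataclass
class CoupledDataset:
    """Two sample matrices with aligned rows (joint observations)."""

    x: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x and y must have the same number of rows")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    @property
    def dims(self) -> tuple[int, int]:
        return self.x.shape[1], self.y.shape[1]


def precision_matrix(rho: float) -> np.ndarray:
    """Precision (inverse covariance) matrix of a unit-variance pair.

    Returns ``1 / (1 - rho**2) * [[1, -rho], [-rho, 1]]``, symmetric
    positive definite for ``|rho| < 1``.
    """
    rho = float(rho)
    if not np.isfinite(rho) or abs(rho) >= 1.0:
        raise ValueError(f"precision matrix is singular for |rho| >= 1, got {rho}")
    return np.array([[1.0, -rho], [-rho, 1.0]]) / (1.0 - rho * rho)


def g_nonlinearity(u, params: SourcePairParams):
    """Log-density nonlinearity G of the coupled-pair model.

    ``G(u) = -(nu + 2)/2 * log(1 + u / (nu - 2)) + const(nu, rho)`` where
    ``u >= 0`` is the squared Mahalanobis norm of the coordinate pair and
    the constant normalizes the bivariate Student-t.  G is strictly
    decreasing and strictly convex in ``u``; ``rho`` enters only through
    the additive offset ``-1/2 log(1 - rho**2)``, the mutual information
    of a Gaussian pair with correlation ``rho`` (in nats).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or not np.all(np.isfinite(u)):
        raise ValueError("u must be finite and nonnegative")
    if params.gaussian:
        # Large-nu limit: G(u) -> -u/2 - log(2 pi) - 1/2 log(1 - rho^2)
        return -0.5 * u - np.log(2 * np.pi) - 0.5 * np.log1p(-params.rho**2)
    nu, rho = params.nu, params.rho
    const = (
        gammaln((nu + 2) / 2)
        - gammaln(nu / 2)
        - np.log((nu - 2) * np.pi)
        - 0.5 * np.log1p(-rho * rho)
    )
    return -(nu + 2) / 2 * np.log1p(u / (nu - 2)) + const


def pair_logdensity(s_pair, params: SourcePairParams):
    """Log pdf of a coupled source pair, ``log p(s1, s2) = G(s' Lambda s)``.

    ``s_pair`` may be a 2-vector or an ``(T, 2)`` array.
    """
    s = np.asarray(s_pair, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite source values")
    rho = params.rho
    s1, s2 = (s[..., 0], s[..., 1])
    u = (s1 * s1 + s2 * s2 - 2.0 * rho * s1 * s2) / (1.0 - rho * rho)
    return g_nonlinearity(u, params)


def sample_coupled_sources(
    params: SourcePairParams, T: int, seed=None
) -> CoupledSourceSample:
    """Draw ``T`` samples of a coupled source pair.

    A correlated standard-Gaussian pair (correlation ``rho``) is scaled
    by the square root of a shared inverse-Gamma variance variable with
    shape ``nu / 2`` and scale ``(nu - 2) / 2``, so each marginal has
    population mean 0 and variance 1 and the pair's linear correlation
    equals ``rho``.  In the Gaussian limit (``nu=None``) the scaling is
    omitted.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    rho = params.rho
    g = rng.standard_normal((int(T), 2))
    z1 = g[:, 0]
    z2 = rho * g[:, 0] + np.sqrt(1.0 - rho * rho) * g[:, 1]
    if params.gaussian:
        s1, s2 = z1, z2
    else:
        nu = params.nu
        # sigma^2 = (nu - 2) / chi2_nu  ~ InvGamma(nu/2, (nu-2)/2); E[sigma^2] = 1
        sigma = np.sqrt((nu - 2.0) / rng.chisquare(nu, int(T)))
        s1, s2 = z1 * sigma, z2 * sigma
    return CoupledSourceSample(
        s_x=s1, s_y=s2, params=params, seed=seed if np.isscalar(seed) else None
    )


def generate_coupled_data(basis: CoupledBasis, T: int, seed=None) -> CoupledDataset:
    """Generate whitened-domain observations ``x = W_x s_x``, ``y = W_y s_y``.

    Source pairs are independent across the ``K`` coupled columns.  When
    ``K < d`` for a set, the orthogonal complement of its features is
    filled with iid standard-Gaussian coordinates so the set is white.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    from scipy.linalg import null_space

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(basis.n_pairs + 2)
    K = basis.n_pairs
    T = int(T)
    S_x = np.empty((T, K))
    S_y = np.empty((T, K))
    for i, p in enumerate(basis.pairs):
        smp = sample_coupled_sources(p, T, seed=children[i])
        S_x[:, i] = smp.s_x
        S_y[:, i] = smp.s_y
    x = S_x @ basis.W_x.T
    y = S_y @ basis.W_y.T
    for W, data, child in ((basis.W_x, x, children[-2]), (basis.W_y, y, children[-1])):
        d = W.shape[0]
        if K < d:
            B = null_space(W.T)
            rng = np.random.default_rng(child)
            data += rng.standard_normal((T, B.shape[1])) @ B.T
    return CoupledDataset(
        x=x,
        y=y,
        meta={
            "seed": seed if np.isscalar(seed) else None,
            "sources_x": S_x,
            "sources_y": S_y,
            "whitened": True,
        },
    )
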