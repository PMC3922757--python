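"""Reference methods HOCCA is compared against: classical CCA on
whitened data, an orthonormal ICA baseline, whitening-only, and greedy
mutual-information matching of independently learned components."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .metrics import mi_histogram
from .model import CoupledBasis, CoupledDataset, SourcePairParams

__all__ = ["MatchResult", "ICAResult", "WhitenedCCA", "OrthogonalICA",
           "fit_cca", "fit_ica", "greedy_match", "whitening_baseline"]

_RHO_CLIP = 1.0 - 1e-9


@dataclass
class MatchResult:
    """Greedy MI pairing of x-components to y-components."""

    pairing: np.ndarray  # pairing[k] = (x_index, y_index), in selection order
    pair_mi: np.ndarray


def fit_cca(data: CoupledDataset) -> CoupledBasis:
    """CCA of two whitened data sets via SVD of the sample
    cross-correlation matrix.

    The left/right singular vectors are the features of each set; the
    singular values are the canonical correlations (stored as pair rhos
    with the shape parameter left at its Gaussian limit), sorted
    non-increasing.  Pairs beyond the rank of the cross-correlation get
    rho = 0 with an arbitrary orthonormal completion.
    """
    T = data.n_samples
    C = data.x.T @ data.y / T
    U, s, Vt = np.linalg.svd(C)
    K = min(data.dims)
    rhos = np.clip(s[:K], 0.0, _RHO_CLIP)
    return CoupledBasis(
        W_x=U[:, :K],
        W_y=Vt[:K].T,
        pairs=[SourcePairParams(rho=r, nu=None) for r in rhos],
        meta={"method": "cca"},
    )


class WhitenedCCA(BaseEstimator):
    """Classical CCA for pre-whitened paired data (sklearn-style)."""

    def __init__(self, n_pairs: int | None = None):
        self.n_pairs = n_pairs

    def fit(self, X, Y):
        data = X if isinstance(X, CoupledDataset) else CoupledDataset(x=X, y=Y)
        basis = fit_cca(data)
        K = self.n_pairs if self.n_pairs is not None else basis.n_pairs
        self.basis_ = CoupledBasis(
            W_x=basis.W_x[:, :K], W_y=basis.W_y[:, :K], pairs=basis.pairs[:K]
        )
        self.components_x_ = self.basis_.W_x
        self.components_y_ = self.basis_.W_y
        self.rhos_ = self.basis_.rhos
        return self

    def transform(self, X, Y):
        return np.asarray(X) @ self.components_x_, np.asarray(Y) @ self.components_y_


@dataclass
class ICAResult:
    components: np.ndarray  # (d, K), orthonormal columns = features
    non_identifiable: bool
    contrast: np.ndarray  # per-component sparsity contrast


_LOGCOSH_GAUSS = 0.3745672966749965  # E[log cosh(g)], g ~ N(0, 1)


def fit_ica(X: np.ndarray, K: int, seed: int = 0) -> ICAResult:
    """Orthonormal ICA of one whitened data set (FastICA, log-cosh).

    Components are sorted by decreasing negentropy contrast
    ``(E[log cosh(s)] - E[log cosh(g)])^2`` and the first ``K`` returned.
    A flat contrast (Gaussian input) is flagged as non-identifiable.
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    if K > d:
        raise ValueError("K cannot exceed the data dimension")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        ica = FastICA(whiten=False, fun="logcosh", random_state=seed, max_iter=400)
        try:
            ica.fit(X)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = FastICA(whiten=False, fun="logcosh", random_state=seed,
                              max_iter=400)
                ica.fit(X)
    W = ica.components_.T  # columns = features (orthonormal for white data)
    # exact re-orthonormalization
    U, _, Vt = np.linalg.svd(W, full_matrices=False)
    W = U @ Vt
    S = X @ W
    contrast = (np.mean(np.log(np.cosh(S)), axis=0) - _LOGCOSH_GAUSS) ** 2
    order = np.argsort(-contrast, kind="stable")
    flat = contrast.max() < 1e-4
    return ICAResult(
        components=W[:, order[:K]],
        non_identifiable=bool(flat or not converged),
        contrast=contrast[order[:K]],
    )


class OrthogonalICA(BaseEstimator):
    """Sparse-contrast ICA under orthonormality for whitened data."""

    def __init__(self, n_components: int | None = None, random_state: int = 0):
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        K = self.n_components if self.n_components is not None else X.shape[1]
        res = fit_ica(X, K, seed=self.random_state)
        self.components_ = res.components
        self.non_identifiable_ = res.non_identifiable
        self.contrast_ = res.contrast
        return self

    def transform(self, X):
        return np.asarray(X) @ self.components_


def greedy_match(mi_matrix: np.ndarray) -> MatchResult:
    """Greedy bijection maximizing per-pair MI.

    Repeatedly selects the globally largest entry of the matrix,
    records its (row, column) pair and removes that row and column.
    Ties break toward the lowest row index, then the lowest column.
    """
    M = np.array(mi_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("mi_matrix must be square")
    if not np.all(np.isfinite(M)):
        raise ValueError("mi_matrix entries must be finite")
    K = M.shape[0]
    pairing = np.empty((K, 2), dtype=int)
    values = np.empty(K)
    work = M.copy()
    for k in range(K):
        i, j = np.unravel_index(np.argmax(work), work.shape)  # row-major argmax
        pairing[k] = (i, j)
        values[k] = M[i, j]
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return MatchResult(pairing=pairing, pair_mi=values)


def whitening_baseline(
    data: CoupledDataset, n_bins: int = 64
) -> tuple[CoupledBasis, MatchResult]:
    """Whitening-only coupled representation.

    Features of both sets are identity coordinates; the correspondence
    is found by greedy MI matching of the empirical coordinates (reduced
    bin count for K x K feasibility).
    """
    d_x, d_y = data.dims
    K = min(d_x, d_y)
    M = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            M[i, j] = mi_histogram(data.x[:, i], data.y[:, j], n_bins=n_bins).value
    match = greedy_match(M)
    order = match.pairing[np.argsort(match.pairing[:, 0])]
    W_x = np.eye(d_x)[:, order[:, 0]]
    W_y = np.eye(d_y)[:, order[:, 1]]
    rhos = [
        np.clip(np.corrcoef(data.x[:, i], data.y[:, j])[0, 1], -_RHO_CLIP, _RHO_CLIP)
        for i, j in order
    ]
    basis = CoupledBasis(
        W_x=W_x,
        W_y=W_y,
        pairs=[SourcePairParams(rho=r, nu=None) for r in rhos],
        meta={"method": "whitening"},
    )
    return basis, match
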