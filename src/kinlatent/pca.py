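"""Principal component analysis with explicit encode/decode and eigenvalue access.

PCA is fit by singular value decomposition of the mean-centered data matrix
(numerically preferable to eigen-decomposing the covariance); eigenvalues of
the covariance are the squared singular values over (m - 1).  A deterministic
sign convention — each loading column's largest-magnitude element is positive
— makes results reproducible across numerics backends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .metrics import LatentRepresentation, DimensionVarianceProfile


class PCAError(ValueError):
    """Raised on invalid PCA inputs or out-of-range component counts."""


@dataclass
class PCAModel:
    """Mean vector, orthonormal loadings (columns by descending eigenvalue),
    and the descending covariance eigenvalues."""

    mean: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.loadings.shape[0]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mean": self.mean.tolist(),
                    "loadings": self.loadings.tolist(),
                    "eigenvalues": self.eigenvalues.tolist(),
                    "ordering": "columns by descending eigenvalue",
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
        )


def fit_pca(X: np.ndarray) -> PCAModel:
    """Fit PCA on the mean-centered sample matrix via full SVD.

    The loadings form a complete orthonormal basis of channel space even when
    fewer than ``n_channels`` directions carry variance (trailing eigenvalues
    are then zero).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise PCAError("fit_pca needs a 2-D matrix with at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD when samples outnumber channels (Vt is then the complete
    # c x c basis and the huge n x n U is never formed); full only when the
    # basis would otherwise be incomplete
    _, s, vt = np.linalg.svd(Xc, full_matrices=Xc.shape[0] < Xc.shape[1])
    n_channels = X.shape[1]
    eig = np.zeros(n_channels)
    eig[: len(s)] = s**2 / (X.shape[0] - 1)
    loadings = vt.T
    # Deterministic sign: largest-|.| element of each column made positive.
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(n_channels)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    return PCAModel(mean=mean, loadings=loadings, eigenvalues=eig)


def _check_k(model: PCAModel, k: int) -> None:
    if not 1 <= k <= model.n_channels:
        raise PCAError(f"k must lie in [1, {model.n_channels}]; got {k}")


def pca_encode(model: PCAModel, X: np.ndarray, k: int) -> LatentRepresentation:
    """Project onto the first k principal directions: Z = (X - mean) L_k."""
    _check_k(model, k)
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_channels:
        raise PCAError(f"X has {X.shape[1]} channels, model expects {model.n_channels}")
    Z = (X - model.mean) @ model.loadings[:, :k]
    return LatentRepresentation(A=Z, method="PCA")


def pca_decode(model: PCAModel, Z) -> np.ndarray:
    """Reconstruct channel space from k scores: Xhat = Z L_k' + mean."""
    A = Z.A if isinstance(Z, LatentRepresentation) else np.asarray(Z, dtype=float)
    k = A.shape[1]
    _check_k(model, k)
    return A @ model.loadings[:, :k].T + model.mean


def pca_dimension_variance(model: PCAModel, k: int) -> DimensionVarianceProfile:
    """Eigenvalue-route dimension variance: 100 * lambda_i / sum_{j<=k} lambda_j."""
    _check_k(model, k)
    lam = model.eigenvalues[:k]
    total = lam.sum()
    if total <= 0:
        raise PCAError("leading eigenvalues are all zero")
    return DimensionVarianceProfile(v_dim=100.0 * lam / total)
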