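"""Reconstruction and latent-space metrics.

* **VAF** (variance accounted for): percentage of signal variance preserved
  by a reconstruction, ``(1 - var(Y - Yhat) / var(Y)) * 100``; 100% means the
  reconstruction is identical to the input.  The aggregate pools variance
  across channels (``1 - sum_c var(residual_c) / sum_c var(signal_c)``), the
  standard multivariate form; per-channel values are reported alongside.
* **Signal variance**: per-channel sample variance averaged over channels,
  one scalar per dataset.
* **Dimension variance**: each latent coordinate's share of the total latent
  variance, in percent, sorted descending; its max-minus-min is the *range*
  of dimension variance, a measure of how unevenly variance concentrates
  across latent dimensions.

Sample variances use the m-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


class MetricError(ValueError):
    """Raised on shape mismatches or degenerate metric inputs."""


@dataclass
class LatentRepresentation:
    """Samples-by-dimensions matrix of latent scores (PC scores or coding units)."""

    A: np.ndarray
    method: str = "PCA"
    dim_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[1] < 1 or self.A.shape[0] < 1:
            raise MetricError("latent matrix must be (m >= 1) x (n >= 1)")
        if not self.dim_labels:
            prefix = "CU" if self.method.lower() in ("naen", "ae", "autoencoder") else "PC"
            self.dim_labels = [f"{prefix}{i + 1}" for i in range(self.A.shape[1])]

    @property
    def n_dims(self) -> int:
        return self.A.shape[1]


@dataclass
class VAFResult:
    aggregate_vaf: float
    per_channel_vaf: np.ndarray
    n_samples: int
    degenerate_channels: list[int] = field(default_factory=list)


@dataclass
class DimensionVarianceProfile:
    """Percent of latent variance per dimension, sorted descending."""

    v_dim: np.ndarray

    def __post_init__(self) -> None:
        self.v_dim = np.sort(np.asarray(self.v_dim, dtype=float))[::-1]

    @property
    def range(self) -> float:
        return float(self.v_dim[0] - self.v_dim[-1])


def vaf(Y: np.ndarray, Yhat: np.ndarray) -> VAFResult:
    """Variance accounted for by a reconstruction, per channel and pooled."""
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape:
        raise MetricError(f"shape mismatch: {Y.shape} vs {Yhat.shape}")
    if Y.ndim == 1:
        Y, Yhat = Y[:, None], Yhat[:, None]
    if Y.shape[0] < 2:
        raise MetricError("VAF needs at least 2 samples")
    resid_var = np.var(Y - Yhat, axis=0, ddof=1)
    signal_var = np.var(Y, axis=0, ddof=1)
    degenerate = np.flatnonzero(signal_var == 0.0)
    per_channel = np.full(Y.shape[1], np.nan)
    ok = signal_var > 0
    per_channel[ok] = (1.0 - resid_var[ok] / signal_var[ok]) * 100.0
    total_signal = signal_var.sum()
    if total_signal == 0.0:
        raise MetricError("all channels have zero variance")
    aggregate = float((1.0 - resid_var.sum() / total_signal) * 100.0)
    return VAFResult(
        aggregate_vaf=aggregate,
        per_channel_vaf=per_channel,
        n_samples=Y.shape[0],
        degenerate_channels=[int(i) for i in degenerate],
    )


def signal_variance(X: np.ndarray) -> float:
    """Mean over channels of the per-channel sample variance."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise MetricError("signal_variance needs at least 2 samples")
    return float(np.var(X, axis=0, ddof=1).mean())


def dimension_variance(Z) -> DimensionVarianceProfile:
    """Share of latent variance per dimension (percent, descending)."""
    A = Z.A if isinstance(Z, LatentRepresentation) else np.asarray(Z, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise MetricError("latent matrix must have at least 2 rows")
    v = np.var(A, axis=0, ddof=1)
    total = v.sum()
    if total <= 0.0:
        raise MetricError("all latent dimensions have zero variance")
    return DimensionVarianceProfile(v_dim=100.0 * v / total)


def range_of_dimension_variance(profiles) -> float:
    """Mean over profiles (e.g., participants) of max - min dimension variance."""
    profiles = list(profiles)
    if not profiles:
        raise MetricError("need at least one dimension-variance profile")
    return float(np.mean([p.range for p in profiles]))


def linear_r2(x: np.ndarray, y: np.ndarray):
    """Ordinary least-squares line fit: returns (r_squared, slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise MetricError("linear_r2 needs equal-length 1-D vectors of length >= 3")
    if np.ptp(x) == 0.0:
        raise MetricError("x is constant: slope undefined")
    fit = sps.linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope), float(fit.intercept)
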