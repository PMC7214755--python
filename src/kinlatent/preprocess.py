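"""Preprocessing chain for kinematic recordings.

The canonical order is: Butterworth low-pass (first order, 10 Hz cutoff by
default), removal of REST-phase samples, global absolute-maximum
normalization, then an 80/20 holdout split.  Filtering is zero-phase
(forward-backward) by default so posture labels stay aligned with the
signal; a causal mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.model_selection import KFold

from .recording import ACTIVE, KinematicRecording


class PreprocessError(ValueError):
    """Raised on invalid preprocessing parameters or degenerate inputs."""


@dataclass
class NormalizedDataset:
    """A normalized sample matrix plus carried-over labels and split indices.

    ``scale`` is the single absolute-maximum value the whole dataset was
    divided by; after normalization ``max |X| == 1`` when the scale came from
    this dataset itself.
    """

    X: np.ndarray
    scale: float
    movement_class: np.ndarray
    trial_id: np.ndarray
    dataset_tag: str = "SYNTH"
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    def split(self, frac: float = 0.8, seed: int = 0) -> "NormalizedDataset":
        """Attach a seeded holdout split (in place) and return self."""
        self.train_idx, self.test_idx = holdout_split(self.n_samples, frac, seed)
        return self


def butterworth_lowpass(
    rec: KinematicRecording,
    cutoff_hz: float = 10.0,
    order: int = 1,
    zero_phase: bool = True,
) -> KinematicRecording:
    """Low-pass every channel with a digital Butterworth filter.

    Zero-phase application (``filtfilt``) squares the magnitude response, so
    a first-order filter attenuates a sinusoid at the cutoff by 0.5 rather
    than 1/sqrt(2); it introduces no lag, which keeps the REST/ACTIVE labels
    aligned.  Set ``zero_phase=False`` for a causal single pass.
    """
    nyquist = rec.sample_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise PreprocessError(
            f"cutoff_hz must lie in (0, {nyquist}) for sample rate "
            f"{rec.sample_rate_hz} Hz; got {cutoff_hz}"
        )
    if order < 1:
        raise PreprocessError("order must be >= 1")
    b, a = signal.butter(order, cutoff_hz, btype="low", fs=rec.sample_rate_hz)
    if zero_phase:
        filtered = signal.filtfilt(b, a, rec.samples, axis=0)
    else:
        filtered = signal.lfilter(b, a, rec.samples, axis=0)
    return rec.with_samples(filtered)


def remove_rest(rec: KinematicRecording) -> KinematicRecording:
    """Keep only ACTIVE-phase samples, preserving order."""
    mask = rec.phase == ACTIVE
    if not mask.any():
        raise PreprocessError("recording contains no ACTIVE samples")
    return rec.take(np.flatnonzero(mask))


def normalize_global_absmax(
    rec: KinematicRecording, scale: float | None = None
) -> NormalizedDataset:
    """Normalize by the single absolute maximum across all channels and samples.

    One scalar per dataset, so relative amplitudes between channels are
    preserved.  Pass ``scale`` to reuse another dataset's scale (e.g., a
    train-only scale for leakage-free workflows); by default the scale is
    computed from this dataset.
    """
    if scale is None:
        scale = float(np.max(np.abs(rec.samples)))
        if scale == 0.0:
            raise PreprocessError("all-zero recording: normalization scale is degenerate")
    elif scale <= 0:
        raise PreprocessError("external normalization scale must be positive")
    return NormalizedDataset(
        X=rec.samples / scale,
        scale=scale,
        movement_class=rec.movement_class.copy(),
        trial_id=rec.trial_id.copy(),
        dataset_tag=rec.dataset_tag,
    )


def holdout_split(n_samples: int, frac: float = 0.8, seed: int = 0):
    """Seeded uniformly-random disjoint train/test partition at sample level."""
    if n_samples < 2:
        raise PreprocessError("holdout_split needs at least 2 samples")
    if not 0 < frac < 1:
        raise PreprocessError("frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    n_train = int(round(frac * n_samples))
    n_train = min(max(n_train, 1), n_samples - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def trial_holdout_split(trial_id: np.ndarray, frac: float = 0.8, seed: int = 0):
    """Holdout at trial level: whole trials go to train or test.

    Sample-level splitting leaks within-trial autocorrelation across the
    split; this variant avoids that at the cost of coarser split fractions.
    """
    trials = np.unique(trial_id)
    if len(trials) < 2:
        raise PreprocessError("trial-level holdout needs at least 2 trials")
    tr, te = holdout_split(len(trials), frac, seed)
    train_mask = np.isin(trial_id, trials[tr])
    return np.flatnonzero(train_mask), np.flatnonzero(~train_mask)


def kfold_indices(n_samples: int, k: int = 5, seed: int = 0):
    """Seeded shuffled k-fold partition; fold sizes differ by at most one."""
    if k < 2:
        raise PreprocessError("k must be >= 2")
    if k > n_samples:
        raise PreprocessError(f"k={k} exceeds n_samples={n_samples}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(np.arange(n_samples))]
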