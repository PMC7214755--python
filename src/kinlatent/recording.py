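"""Labeled multichannel joint-angle recordings and their CSV representation.

A :class:`KinematicRecording` is the package's central data container: a
``(n_samples, n_channels)`` matrix of joint-angle values plus per-sample
labels for movement class, trial number, and REST/ACTIVE phase.  Recordings
round-trip through a plain CSV schema::

    time_s, ch01..chNN, movement_class, trial_id, phase, participant_id, dataset_tag

with one row per sample and phase in {REST, ACTIVE}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REST = "REST"
ACTIVE = "ACTIVE"
_PHASES = frozenset({REST, ACTIVE})
_LABEL_COLUMNS = ("movement_class", "trial_id", "phase", "participant_id", "dataset_tag")


class RecordingError(Exception):
    """Base class for recording container and file errors."""


class RecordingParseError(RecordingError):
    """Raised when a recording file cannot be parsed at all."""


class RecordingSchemaError(RecordingError):
    """Raised when a parsed file disagrees with the declared schema."""


@dataclass
class KinematicRecording:
    """A labeled multichannel joint-angle time series.

    Parameters
    ----------
    samples
        ``(n_samples, n_channels)`` array of joint-angle values.  Units are
        whatever the acquisition device produced (degrees or arbitrary glove
        units); all downstream analysis normalizes them away.
    sample_rate_hz
        Sampling frequency in Hz.
    channel_names
        One identifier per channel.
    movement_class, trial_id, phase
        Per-sample labels: categorical movement name, integer trial counter,
        and REST/ACTIVE phase tag.
    """

    samples: np.ndarray
    sample_rate_hz: float
    channel_names: list[str] = field(default_factory=list)
    movement_class: np.ndarray = None
    trial_id: np.ndarray = None
    phase: np.ndarray = None
    participant_id: str = "P1"
    dataset_tag: str = "SYNTH"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise RecordingError("samples must be a 2-D (n_samples, n_channels) array")
        n = self.samples.shape[0]
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise RecordingSchemaError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )
        for name in ("movement_class", "trial_id", "phase"):
            value = getattr(self, name)
            if value is None:
                raise RecordingError(f"per-sample label array {name!r} is required")
            value = np.asarray(value)
            if value.shape != (n,):
                raise RecordingError(
                    f"label {name!r} has length {value.shape}, expected ({n},)"
                )
            setattr(self, name, value)
        self.trial_id = self.trial_id.astype(int)
        bad = set(np.unique(self.phase)) - _PHASES
        if bad:
            raise RecordingError(f"phase labels must be REST/ACTIVE, got {sorted(bad)}")
        if self.sample_rate_hz <= 0:
            raise RecordingError("sample_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def take(self, index: np.ndarray) -> "KinematicRecording":
        """Return a new recording restricted to the given sample indices."""
        return replace(
            self,
            samples=self.samples[index],
            movement_class=self.movement_class[index],
            trial_id=self.trial_id[index],
            phase=self.phase[index],
        )

    def with_samples(self, samples: np.ndarray) -> "KinematicRecording":
        """Return a copy carrying new sample values but identical labels."""
        samples = np.asarray(samples, dtype=float)
        if samples.shape != self.samples.shape:
            raise RecordingError("replacement samples must keep the original shape")
        return replace(self, samples=samples)


def write_recording(rec: KinematicRecording, path) -> None:
    """Write a recording to CSV under the package's flat one-row-per-sample schema."""
    t = np.arange(rec.n_samples) / rec.sample_rate_hz
    frame = pd.DataFrame({"time_s": t})
    for j, name in enumerate(rec.channel_names):
        frame[name] = rec.samples[:, j]
    frame["movement_class"] = rec.movement_class
    frame["trial_id"] = rec.trial_id
    frame["phase"] = rec.phase
    frame["participant_id"] = rec.participant_id
    frame["dataset_tag"] = rec.dataset_tag
    frame.to_csv(path, index=False, float_format="%.10g")


def read_recording(path, sample_rate_hz: float | None = None) -> KinematicRecording:
    """Read a recording written by :func:`write_recording`.

    The sample rate is recovered from the ``time_s`` column unless given
    explicitly.  Malformed files raise :class:`RecordingParseError` (with the
    offending line where pandas reports one); files whose rows disagree with
    the declared header raise :class:`RecordingSchemaError`.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise RecordingParseError(f"{path}: empty or headerless file") from exc
    except pd.errors.ParserError as exc:
        raise RecordingParseError(f"{path}: {exc}") from exc
    if frame.empty:
        raise RecordingParseError(f"{path}: no data rows")

    missing = [c for c in ("time_s", *_LABEL_COLUMNS) if c not in frame.columns]
    if missing:
        raise RecordingSchemaError(f"{path}: missing required columns {missing}")
    channel_names = [
        c for c in frame.columns if c not in ("time_s", *_LABEL_COLUMNS)
    ]
    if not channel_names:
        raise RecordingSchemaError(f"{path}: no channel columns between time_s and labels")

    values = frame[channel_names].to_numpy(dtype=float)
    if np.isnan(values).any():
        row = int(np.argwhere(np.isnan(values).any(axis=1))[0, 0])
        raise RecordingSchemaError(
            f"{path}: row {row + 2} has fewer channel values than the header declares "
            f"({len(channel_names)} channels expected)"
        )

    if sample_rate_hz is None:
        t = frame["time_s"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.median(np.diff(t))
            if dt <= 0:
                raise RecordingSchemaError(f"{path}: non-increasing time_s column")
            sample_rate_hz = 1.0 / dt
        else:
            sample_rate_hz = 1.0

    return KinematicRecording(
        samples=values,
        sample_rate_hz=float(sample_rate_hz),
        channel_names=channel_names,
        movement_class=frame["movement_class"].to_numpy(dtype=str),
        trial_id=frame["trial_id"].to_numpy(dtype=int),
        phase=frame["phase"].to_numpy(dtype=str),
        participant_id=str(frame["participant_id"].iloc[0]),
        dataset_tag=str(frame["dataset_tag"].iloc[0]),
    )
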