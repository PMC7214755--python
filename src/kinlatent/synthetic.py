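"""Synthetic hand-kinematics generator with known latent structure.

Real data-glove recordings of gesture repetitions are rarely deposited, so
this module produces labeled stand-ins whose ground truth is known by
construction: 20 correlated joint-angle channels driven by a low-dimensional
latent process, with trials that ramp from a REST posture to a class-specific
ACTIVE posture and back, and a switchable linear vs. non-linear
latent-to-channel map.  Because the intrinsic dimensionality, the
(non)linearity, and the class structure are all chosen by the caller, the
generator serves as an oracle for dimensionality-reduction experiments:
a linear method must be exact on ``map_kind="linear"`` noise-free data and
must lose variance on ``map_kind="nonlinear"`` data of the same intrinsic
dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import ACTIVE, REST, KinematicRecording


class SpecError(ValueError):
    """Raised when a :class:`SyntheticSpec` violates its preconditions."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic participant's recording session.

    Defaults emulate a gesture-repetition protocol: 10 movement classes,
    10 repetitions (trials) each, a 3 s ACTIVE hold per trial at 100 Hz,
    and 20 glove channels driven by a 2-D latent process.

    ``noise_sd`` is additive i.i.d. Gaussian sensor noise in the same
    (arbitrary, unit-scale) units as the channel signal.  ``class_separation``
    scales the distance between class target postures in latent space.
    ``warp_amplitude`` scales the gain of the per-channel sinusoidal warp
    applied on top of the linear mix when ``map_kind="nonlinear"``; it bends
    the latent manifold without changing its intrinsic dimension, so linear
    methods lose reconstruction variance while a nonlinear method need not.
    The default of 2.0 places the two-component linear reconstruction of
    noise-free data in the low-80s-percent VAF band observed for real
    whole-hand kinematics.
    """

    n_classes: int = 10
    trials_per_class: int = 10
    latent_dim: int = 2
    map_kind: str = "nonlinear"
    noise_sd: float = 0.02
    class_separation: float = 1.0
    active_duration_s: float = 3.0
    rest_duration_s: float = 2.0
    ramp_duration_s: float = 0.5
    sample_rate_hz: float = 100.0
    n_channels: int = 20
    warp_amplitude: float = 2.0
    trial_jitter_sd: float = 0.05
    wander_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise SpecError("n_classes must be >= 2")
        if self.trials_per_class < 1:
            raise SpecError("trials_per_class must be >= 1")
        if self.latent_dim < 1:
            raise SpecError("latent_dim must be >= 1")
        if self.latent_dim > self.n_channels:
            raise SpecError("latent_dim must not exceed n_channels")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.sample_rate_hz <= 0:
            raise SpecError("sample_rate_hz must be > 0")
        for name in ("active_duration_s", "rest_duration_s", "ramp_duration_s"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be > 0")
        if self.map_kind not in ("linear", "nonlinear"):
            raise SpecError("map_kind must be 'linear' or 'nonlinear'")


def _sigmoid_ramp(n: int) -> np.ndarray:
    """Smooth 0 -> 1 ramp of n samples (logistic, ~1e-3 end error)."""
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    return 1.0 / (1.0 + np.exp(-14.0 * (t - 0.5)))


def _latent_to_channels(spec: SyntheticSpec, z: np.ndarray, rng_map: np.random.Generator):
    """Map latent trajectories to channel space with a fixed seeded map.

    The linear map mixes the latent coordinates through unit-norm random
    channel directions.  The nonlinear map additionally pushes each channel
    through its own smooth bounded sinusoidal warp ``sin(g_c u + phi_c)``
    with a seeded gain and phase per channel, so the data lie on a curved
    manifold of the same intrinsic dimension.  A non-monotone warp is used
    deliberately: monotone saturations of a low-dimensional linear mix keep
    most of their linear correlation with the latent subspace (the arcsine-
    law effect), whereas sinusoidal channel responses bend the manifold
    enough that a linear method genuinely underestimates it — the geometry
    attributed to whole-hand joint-angle data, where a channel's excursion
    can rise and fall again within one coordinated movement.
    """
    mix = rng_map.standard_normal((spec.n_channels, spec.latent_dim))
    mix /= np.linalg.norm(mix, axis=1, keepdims=True)
    u = z @ mix.T
    if spec.map_kind == "linear":
        return u
    gains = spec.warp_amplitude * rng_map.uniform(0.5, 1.0, size=spec.n_channels)
    phases = rng_map.uniform(0.0, 2.0 * np.pi, size=spec.n_channels)
    return np.sin(gains * u + phases)


def generate_dataset(spec: SyntheticSpec) -> KinematicRecording:
    """Generate one participant's labeled synthetic recording.

    Every trial is REST hold -> sigmoidal ramp -> ACTIVE hold -> ramp back;
    only the hold at the class target is tagged ACTIVE, matching protocols in
    which the participant maintains the gesture for a fixed cue interval.
    The same spec (including seed) always produces bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    # Separate stream for the map so the manifold geometry is a function of
    # the seed alone, not of how many trajectory draws preceded it.
    rng_map = np.random.default_rng((spec.seed, 0xA11CE))

    fs = spec.sample_rate_hz
    n_rest = max(1, int(round(spec.rest_duration_s * fs)))
    n_ramp = max(1, int(round(spec.ramp_duration_s * fs)))
    n_active = max(1, int(round(spec.active_duration_s * fs)))
    ramp = _sigmoid_ramp(n_ramp)

    # Class targets: fixed unit-scale directions drawn once, then scaled by
    # class_separation, so larger separation strictly dilates the layout.
    base_targets = rng.standard_normal((spec.n_classes, spec.latent_dim))
    targets = spec.class_separation * base_targets

    z_rows, cls_rows, trial_rows, phase_rows = [], [], [], []
    trial_counter = 0
    for c in range(spec.n_classes):
        for _ in range(spec.trials_per_class):
            trial_counter += 1
            target = targets[c] + spec.trial_jitter_sd * rng.standard_normal(
                spec.latent_dim
            )
            profile = np.concatenate(
                [np.zeros(n_rest), ramp, np.ones(n_active), 1.0 - ramp]
            )
            z = profile[:, None] * target[None, :]
            # Slow within-trial wander: smoothed latent noise, models small
            # postural drift while the gesture is held.
            wander = rng.standard_normal((len(profile), spec.latent_dim))
            width = max(1, int(fs / 4))
            kernel = np.ones(width) / width
            for d in range(spec.latent_dim):
                wander[:, d] = np.convolve(wander[:, d], kernel, mode="same")
            z = z + spec.wander_sd * wander
            phase = np.array(
                [REST] * n_rest + [REST] * n_ramp + [ACTIVE] * n_active + [REST] * n_ramp
            )
            z_rows.append(z)
            cls_rows.append(np.full(len(profile), f"class{c:02d}"))
            trial_rows.append(np.full(len(profile), trial_counter))
            phase_rows.append(phase)

    z_all = np.vstack(z_rows)
    x = _latent_to_channels(spec, z_all, rng_map)
    if spec.noise_sd > 0:
        x = x + spec.noise_sd * rng.standard_normal(x.shape)

    return KinematicRecording(
        samples=x,
        sample_rate_hz=fs,
        movement_class=np.concatenate(cls_rows),
        trial_id=np.concatenate(trial_rows),
        phase=np.concatenate(phase_rows),
        participant_id=f"SYN{spec.seed}",
        dataset_tag="SYNTH",
    )
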