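"""Generate a synthetic hand-kinematics recording and preview its structure.

Builds one synthetic participant: 6 movement classes x 3 trials of
20-channel joint-angle data driven by a 2-D latent process, each trial
ramping from REST to a class posture and back.
"""

import numpy as np

from kinlatent import SyntheticSpec, generate_dataset, write_recording

spec = SyntheticSpec(
    n_classes=6,
    trials_per_class=3,
    active_duration_s=1.5,
    rest_duration_s=1.0,
    ramp_duration_s=0.4,
    seed=0,
)
rec = generate_dataset(spec)

print(f"samples x channels : {rec.samples.shape}")
print(f"sample rate        : {rec.sample_rate_hz} Hz")
print(f"movement classes   : {sorted(map(str, set(rec.movement_class)))}")
print(f"trials             : {rec.trial_id.max()}")
active = rec.phase == "ACTIVE"
print(f"ACTIVE fraction    : {active.mean():.2f}")
print(f"channel value range: [{rec.samples.min():.2f}, {rec.samples.max():.2f}]")

write_recording(rec, "scratch_recording.csv")
print("wrote scratch_recording.csv (CSV schema: time_s, ch01.., labels)")

# every trial holds the gesture for active_duration_s * sample_rate_hz samples
per_trial = np.bincount(rec.trial_id[active])[1:]
print(f"ACTIVE samples per trial: {per_trial.min()}..{per_trial.max()} (expected 150)")
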