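import numpy as np
import pytest
from dataclasses import replace

from kinlatent import (
    SyntheticSpec,
    generate_dataset,
    normalize_global_absmax,
    remove_rest,
)

# Scaled-down session spec: same protocol shape as the full defaults
# (REST -> ramp -> 3 s hold -> ramp, 100 Hz, 20 channels) but fewer/shorter
# trials so model fits stay fast.
SMALL_SPEC = SyntheticSpec(
    n_classes=6,
    trials_per_class=3,
    active_duration_s=1.5,
    rest_duration_s=1.0,
    ramp_duration_s=0.4,
    seed=7,
)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def nonlinear_active():
    """Normalized ACTIVE-phase dataset from the nonlinear generator."""
    rec = remove_rest(generate_dataset(replace(SMALL_SPEC, map_kind="nonlinear")))
    return normalize_global_absmax(rec)


@pytest.fixture(scope="session")
def linear_clean_active():
    """Noise-free linear-map dataset: data lie exactly in a 2-D affine subspace."""
    rec = remove_rest(
        generate_dataset(replace(SMALL_SPEC, map_kind="linear", noise_sd=0.0))
    )
    return normalize_global_absmax(rec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
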