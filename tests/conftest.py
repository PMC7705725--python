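import dataclasses

import numpy as np
import pytest

from lesionscope import CohortConfig
from lesionscope.synthetic_cohort import generate_brain_volume


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Desk-scale grid that still carries the full layer topology."""
    return CohortConfig(grid_shape=(96, 72, 72), n_control=3, n_lesion=2, master_seed=7)


@pytest.fixture(scope="session")
def clean_config(small_config) -> CohortConfig:
    """Noise- and jitter-free variant for exact-geometry checks."""
    return dataclasses.replace(
        small_config, noise_sd=0.0, pose_jitter_deg=0.0, pose_jitter_vox=0.0
    )


@pytest.fixture(scope="session")
def control_subject(small_config):
    return generate_brain_volume(small_config, subject_seed=101, subject_id="s0")


@pytest.fixture(scope="session")
def clean_subject(clean_config):
    return generate_brain_volume(clean_config, subject_seed=202, subject_id="c0")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
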