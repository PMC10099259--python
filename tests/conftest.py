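import numpy as np
import pytest

from solegrf.synthgait import (
    SubjectProfile,
    SyntheticConfig,
    generate_dataset,
    generate_trial,
    make_subject,
)


@pytest.fixture
def reference_subject() -> SubjectProfile:
    """A canonical different-timing subject, BW 700 N, stance 0.59 s."""
    return SubjectProfile(
        subject_id="ref",
        body_weight=700.0,
        stance_duration=0.59,
        ap_crossing_phase=0.5,
        met5_center=0.60,
        met1_center=0.72,
        channel_gains=(0.55, 0.45, 0.25),
        timing_group="different",
    )


@pytest.fixture
def noiseless_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_subjects=1, trials_per_subject=1, seed=0, swing_noise_sd=0.0, sensor_noise_sd=0.0
    )


@pytest.fixture
def noiseless_trial(reference_subject, noiseless_config):
    rng = np.random.default_rng(12)
    return generate_trial(reference_subject, noiseless_config, rng)


@pytest.fixture(scope="session")
def small_dataset():
    """A small default-noise cohort shared across tests."""
    return generate_dataset(SyntheticConfig(n_subjects=8, trials_per_subject=2, seed=5))
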