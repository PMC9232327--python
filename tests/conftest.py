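import numpy as np
import pytest

from armbiomech import kinematics as kin
from armbiomech import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_config():
    """Study configuration with all stochastic terms switched off."""
    return syn.CohortConfig(
        coord_noise_sd=0.0, emg_noise_sd=0.0, subject_amplitude_sd=0.0
    )


@pytest.fixture
def default_config():
    return syn.CohortConfig(seed=7)


@pytest.fixture
def subject_a():
    return syn.SubjectProfile(subject_id="A01", group="A", height=1.77)


@pytest.fixture
def subject_b():
    return syn.SubjectProfile(subject_id="B01", group="B", height=1.77)


def random_trajectory(rng, n=50, frame_rate=30.0):
    """Uniformly sampled random walk in the unit cube."""
    return kin.TrajectorySeries(
        timestamps=np.arange(n) / frame_rate,
        positions=rng.uniform(0.0, 1.0, size=(n, 3)),
        frame_rate=frame_rate,
    )
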