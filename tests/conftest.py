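import numpy as np
import pytest

from pocketlab import (NoiseModel, ParticipantProfile, TaskConfig,
                       generate_oddball_schedule)


@pytest.fixture(scope="session")
def default_schedule():
    return generate_oddball_schedule(TaskConfig(seed=0))


@pytest.fixture(scope="session")
def profile():
    return ParticipantProfile()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_noise():
    """Noise model with every stochastic component switched off."""
    return NoiseModel(
        eeg_background_sd=0.0, eeg_line_amp=0.0,
        systemic_amps={"cardiac": 0.0, "resp": 0.0, "mayer": 0.0,
                       "skin": 0.0},
        motion_spike_rate=0.0, motion_shift_rate=0.0,
        intensity_noise_od=0.0, eeg_bad_impedance_fraction=0.0,
        sci_fail_fraction=0.0)
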