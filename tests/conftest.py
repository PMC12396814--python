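import numpy as np
import pytest

from ramplight import synth
from ramplight.task import SHORT_ITI_SPEC, TrialConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def short_config():
    return TrialConfig(iti_spec=SHORT_ITI_SPEC, n_trials=20)


@pytest.fixture(scope="session")
def sd_session_noiseless():
    """Short-ITI dynamic-tone synthetic session, no noise or jitter, dip off."""
    gt = synth.condition_ground_truth(
        "SD", slope_jitter_sd=0.0, dip_amplitude=0.0, n_trials=25, seed=11
    )
    return synth.generate_photometry_session(gt)


@pytest.fixture(scope="session")
def sd_session_noisy():
    gt = synth.condition_ground_truth(
        "SD", noise_sd_405=0.3, noise_sd_470=0.3, n_trials=120, seed=7
    )
    return synth.generate_photometry_session(gt)
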