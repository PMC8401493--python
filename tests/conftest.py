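import numpy as np
import pytest

from ecgrecon import NoiseConfig, make_synthetic_record


@pytest.fixture(scope="session")
def clean_record():
    """30 s noiseless 'normal' synthetic record plus annotations."""
    return make_synthetic_record(
        "normal", duration_s=30, sampling_rate=1000,
        noise=NoiseConfig(white_noise_uv=0, baseline_amp_uv=0), seed=11)


@pytest.fixture(scope="session")
def noisy_record():
    """30 s 'normal' record with the default ambulatory noise model."""
    return make_synthetic_record(
        "normal", duration_s=30, sampling_rate=1000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
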