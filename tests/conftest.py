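import numpy as np
import pytest

from neurocodec import GeneratorConfig, generate_recording


@pytest.fixture(scope="session")
def short_recording():
    """2 s single-channel recording at the default 60 spikes/s regime."""
    cfg = GeneratorConfig(duration_s=2.0, seed=11)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def quiet_multichannel():
    """4-channel spike-free noise recording for codec plumbing tests."""
    cfg = GeneratorConfig(n_channels=4, duration_s=0.2, firing_rate_hz=0.0, noise_sd=4.0, seed=3)
    rec, _ = generate_recording(cfg)
    return rec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
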