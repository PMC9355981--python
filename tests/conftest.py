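import numpy as np
import pytest

from paraseg.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom_cfg():
    return PhantomConfig()


@pytest.fixture(scope="session")
def phantom_pair(phantom_cfg):
    """One deterministic noisy phantom (image, mask)."""
    return generate_phantom(phantom_cfg, 0)


@pytest.fixture(scope="session")
def clean_phantom_pair():
    """Noise-free, bias-free, speckle-free phantom: piecewise constant."""
    cfg = PhantomConfig(fat_fraction_range=(0.0, 0.0), bias_amplitude=0.0,
                        noise_sd=0.0)
    return generate_phantom(cfg, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
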