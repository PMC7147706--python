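import numpy as np
import pytest
from hypothesis import settings

from dermoseg import SynthConfig, generate_lesion_image

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def clean_config() -> SynthConfig:
    """Hair-free, noise-free generator settings for crisp pixel-level checks."""
    return SynthConfig(n_hairs=0, noise_sd=0.0, border_irregularity=0.0, seed=11)


@pytest.fixture(scope="session")
def lesion_pair(clean_config):
    return generate_lesion_image(clean_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
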