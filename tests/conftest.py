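import numpy as np
import pytest

from megdiverge.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale session: enough words for stable correlations, small
    enough that every stage runs in well under a second."""
    return SimConfig(
        n_words=400,
        n_sentences=80,
        n_channels=8,
        n_timebins=5,
        embed_dim=10,
        noise_sd=1.0,
        planted_effect=3.0,
        planted_fraction=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
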