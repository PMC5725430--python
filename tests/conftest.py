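import numpy as np
import pytest

from swdeeg.montage import generate_layout
from swdeeg.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def layout256():
    return generate_layout(256, seed=1)


@pytest.fixture(scope="session")
def layout24():
    return generate_layout(24, seed=3)


@pytest.fixture(scope="session")
def small_dataset(layout24):
    """A small strong-effect 2-class dataset (24 channels, 6 subjects)."""
    cfg = SimulationConfig(n_subjects=6, trials_per_class=5, n_channels=24,
                           n_samples=128, effect_scale=5.0, seed=11)
    return cfg, generate_dataset(cfg, layout24)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
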