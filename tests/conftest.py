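import numpy as np
import pytest

from sigold import SimConfig, generate_dataset, load_table2_fixture


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A quick 40-neurite bilateral experiment over 200 sections."""
    return SimConfig(n_neurites=40, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config, n_synapses=30)


@pytest.fixture(scope="session")
def table2():
    """Packaged PDF gold-count fixture (35 neurons x 3 layers)."""
    return load_table2_fixture()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
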