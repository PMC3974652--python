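import numpy as np
import pytest

from mirnome import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(rng_seed=1, n_hairpins=5, n_decoys=5)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return sd.generate_genome(small_config)
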