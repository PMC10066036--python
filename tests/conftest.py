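import numpy as np
import pytest

from phagequant.synthetic import SceneConfig, simulate_scene


@pytest.fixture(scope="session")
def noiseless_config():
    return SceneConfig(n_cells=5, seed=42, gaussian_read_sd=0.0,
                       poisson_scale=0.0, background_level=100.0)


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_config):
    """Small noiseless field: 5 well-separated cells, phages, all channels."""
    return simulate_scene(noiseless_config)


@pytest.fixture(scope="session")
def truth_mask(noiseless_scene):
    return noiseless_scene.labels()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
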