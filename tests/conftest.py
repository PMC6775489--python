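import numpy as np
import pytest

from tenswood import synthetic


@pytest.fixture(scope="session")
def grid():
    return synthetic.default_raman_grid()


@pytest.fixture(scope="session")
def profiles(grid):
    return synthetic.gen_component_profiles(synthetic.DEFAULT_COMPONENTS, grid)


@pytest.fixture(scope="session")
def component_names():
    return [s.name for s in synthetic.DEFAULT_COMPONENTS]


@pytest.fixture(scope="session")
def tw_layout():
    return synthetic.default_layer_layout("TW")


@pytest.fixture(scope="session")
def noiseless_map(tw_layout, profiles, grid, component_names):
    return synthetic.gen_spectral_map(tw_layout, profiles, grid, seed=1,
                                      component_names=component_names)


@pytest.fixture(scope="session")
def noisy_map(tw_layout, profiles, grid, component_names):
    """Study-scale map at 1% noise."""
    return synthetic.gen_spectral_map(tw_layout, profiles, grid,
                                      noise_sd=0.01, seed=2,
                                      component_names=component_names)


def cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
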