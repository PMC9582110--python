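import numpy as np
import pytest

from octfluid.phantom import PhantomConfig, generate_cube


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Desk-scale phantom geometry used across test modules."""
    return PhantomConfig(n_slices=16, height=64, width=64,
                         blob_radius_range=(3, 6), n_fluid_blobs=2, seed=11)


@pytest.fixture(scope="session")
def small_cube(small_config):
    return generate_cube(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
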