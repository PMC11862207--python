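import warnings

import numpy as np
import pytest

from oroinvade.synthworld import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact deterministic world shared by read-only tests."""
    cfg = WorldConfig(
        seed=3,
        n_mountains=20,
        n_species_pool=60,
        raster_resolution=0.5,
        grid_extent=(0.0, 0.0, 25.0, 25.0),
        climate_years=10,
        n_pas=30,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_world(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
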