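"""Shared fixtures: one small but fully structured synthetic world.

Session-scoped so the landscape/pool/inputs are generated once; tests must
not mutate them (simulation steps return new objects, so this is natural).
"""

import numpy as np
import pytest

from triadscape.experiment import ExperimentConfig, prepare_inputs
from triadscape.growth import generate_growth_tables
from triadscape.landscape import generate_landscape
from triadscape.species import generate_species_pool


@pytest.fixture(scope="session")
def pool():
    return generate_species_pool(17, 5, rng_seed=1)


@pytest.fixture(scope="session")
def growth(pool):
    return generate_growth_tables(pool, n_ecoregions=4, rng_seed=2)


@pytest.fixture(scope="session")
def small_landscape():
    # 40 x 50 = 2,000 ha: large enough for stands, patches and both fire regions
    return generate_landscape(40, 50, stand_mean_size=20, rng_seed=3)


@pytest.fixture(scope="session")
def small_config():
    return ExperimentConfig(n_rows=30, n_cols=40)


@pytest.fixture(scope="session")
def inputs(small_config):
    """Shared simulation inputs on a 1,200-cell landscape."""
    return prepare_inputs(small_config, master_seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
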