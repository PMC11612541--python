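import numpy as np
import pytest

from stressbiomes.config import WorldConfig
from stressbiomes.grid_aggregation import aggregate_assemblages
from stressbiomes.synthetic_data import generate_world


@pytest.fixture(scope="session")
def default_world():
    """The default synthetic world (study conditions), seed 1."""
    cfg = WorldConfig(seed=1)
    species, grid, landscape, occurrences, meta = generate_world(cfg)
    return cfg, species, grid, landscape, occurrences


@pytest.fixture(scope="session")
def default_assemblages(default_world):
    cfg, species, grid, landscape, occurrences = default_world
    return aggregate_assemblages(occurrences, species, grid, landscape, min_species=3)


@pytest.fixture(scope="session")
def small_world():
    """A reduced world for the fast pipeline tests."""
    cfg = WorldConfig(
        seed=7,
        n_species={
            "deciduous_angiosperm": 180,
            "evergreen_angiosperm": 90,
            "evergreen_gymnosperm": 70,
        },
        extent=(0.0, 0.0, 1.4e6, 1.5e6),
    )
    species, grid, landscape, occurrences, meta = generate_world(cfg)
    return cfg, species, grid, landscape, occurrences


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
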