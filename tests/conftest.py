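import numpy as np
import pandas as pd
import pytest

from herpatlas.geoio import OccurrenceTable, RasterGrid
from herpatlas.synthetic import ScenarioConfig, generate_scenario
from herpatlas.tree import Tree


@pytest.fixture
def balanced_tree() -> Tree:
    """((A:1,B:1):1,(C:1,D:1):1); — total branch length 6."""
    return Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def caterpillar_tree() -> Tree:
    """((A:1,B:1):1,C:2); — the worked fair-proportion example."""
    return Tree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_scenario():
    """A 60x60-pixel, 8-species synthetic world shared across tests."""
    cfg = ScenarioConfig(
        n_pixels=60, n_species=8, records_per_species=40,
        n_rare_species=1, n_introduced=1, n_protected_areas=5, seed=11,
    )
    return generate_scenario(cfg)


@pytest.fixture
def occurrences_df() -> pd.DataFrame:
    return pd.DataFrame({
        "species": ["spA", "spA", "spB"],
        "lon": [55.1, 55.1, 55.3],
        "lat": [25.2, 25.3, 25.2],
        "source": ["x", "x", "y"],
    })


@pytest.fixture
def flat_raster() -> RasterGrid:
    return RasterGrid(0.0, 10.0, 1.0, np.arange(20, dtype=float).reshape(4, 5))


def make_table(rows) -> OccurrenceTable:
    return OccurrenceTable(pd.DataFrame(rows, columns=["species", "lon", "lat"]))
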