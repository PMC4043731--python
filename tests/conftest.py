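import numpy as np
import pandas as pd
import pytest

import phylogerm as pg


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the default (emulated-design) conditions."""
    return pg.generate_dataset(pg.SimulationConfig(rng_seed=5))


@pytest.fixture(scope="session")
def metrics_with_attributes(default_dataset):
    """Species-by-temperature analysis table joined to the attribute factors."""
    tab = pg.metrics_table(default_dataset.observations,
                           unit="species_by_temperature")
    return tab.merge(default_dataset.attributes, on="species", how="left")


@pytest.fixture(scope="session")
def small_tree():
    return pg.simulate_tree(16, 42)


@pytest.fixture()
def three_tip_tree():
    return pg.read_newick("((A:1,B:1):1,C:2);")


def balanced_frame(n_per_cell=4, levels_a=3, levels_b=2, seed=0):
    """Fully crossed balanced factorial with additive effects plus noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(levels_a):
        for j in range(levels_b):
            for _ in range(n_per_cell):
                rows.append({"A": f"a{i}", "B": f"b{j}",
                             "y": i * 0.8 - j * 0.5 + rng.normal()})
    return pd.DataFrame(rows)
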