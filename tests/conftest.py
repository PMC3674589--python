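import numpy as np
import pandas as pd
import pytest

from coexnet.synthdata import SyntheticDesign, simulate_dataset, simulate_species_pair


@pytest.fixture(scope="session")
def default_design():
    return SyntheticDesign()


@pytest.fixture(scope="session")
def small_design():
    """Four small modules, two trait-linked, one preserved; quick to simulate."""
    return SyntheticDesign(
        n_modules=4,
        module_sizes=(40, 30, 30, 30),
        n_background_genes=70,
        trait_effects=(1.0, -0.8, 0.0, 0.0),
        preserved_flags=(True, False, False, False),
        probes_per_gene=2,
        seed=0,
    )


@pytest.fixture(scope="session")
def human_dataset(small_design):
    return simulate_dataset(small_design, "human", seed=11)


@pytest.fixture(scope="session")
def species_pair(small_design):
    return simulate_species_pair(small_design, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_expression(rng):
    """Unstructured 20-gene x 10-sample matrix."""
    x = rng.standard_normal((20, 10))
    return pd.DataFrame(
        x,
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{j}" for j in range(10)],
    )
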