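import numpy as np
import pandas as pd
import pytest

from mirindex import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One seeded default-size synthetic study shared across tests."""
    config = SimulationConfig(seed=11, n_genes=60, n_proteins=20)
    return simulate_study(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_group_labels():
    def make(n1, n2, names=("YA", "MA")):
        return pd.Series([names[0]] * n1 + [names[1]] * n2)

    return make
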