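import numpy as np
import pandas as pd
import pytest

from cernanet.config import RunConfig
from cernanet.simulate import (DEFAULT_GROUP_NAMES, SimulationParams,
                               simulate_counts, simulate_design,
                               simulate_sequences)


@pytest.fixture(scope="session")
def design():
    return simulate_design(4, 3, 0, group_names=DEFAULT_GROUP_NAMES)


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale generator settings used by most integration tests."""
    return SimulationParams(n_mrna=60, n_circ=20, n_mir=15, n_axes=4)


@pytest.fixture(scope="session")
def dataset(design, small_params):
    """One fixed synthetic dataset: (matrices, truth, sequences)."""
    matrices, truth = simulate_counts(design, small_params, seed=11)
    sequences = simulate_sequences(truth, seed=12, params=small_params)
    return matrices, truth, sequences


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_counts():
    """Tiny deterministic counts matrix with two groups of two."""
    data = {
        "A_r1": [10, 100, 40, 5],
        "A_r2": [12, 90, 44, 6],
        "B_r1": [50, 95, 42, 4],
        "B_r2": [55, 105, 38, 7],
    }
    m = pd.DataFrame(data, index=[f"g{i}" for i in range(4)])
    d = pd.DataFrame({
        "sample_id": list(data),
        "group": ["A", "A", "B", "B"],
    })
    return m, d
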