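import logging

import numpy as np
import pandas as pd
import pytest

from spotdec import simulation

logging.getLogger("spotdec").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_fixture():
    """Small synthetic tissue + external reference shared across tests."""
    return simulation.make_fixture(
        n_types=3, n_cells=400, n_genes=60, n_markers_per_type=6, seed=0
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_fixture):
    sc, _, _ = tiny_fixture
    return simulation.coarse_grain(sc, grid_size=100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def grid5x5():
    ids = [f"s{i}" for i in range(25)]
    xy = np.array([[i % 5, i // 5] for i in range(25)], dtype=float)
    return pd.DataFrame(xy, index=ids, columns=["x", "y"])
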