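import numpy as np
import pytest

from spotweight import CountsDataset, SimConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dataset(rng, n=20, G=8, max_count=12):
    counts = rng.integers(0, max_count, size=(n, G))
    coords = rng.uniform(0, 100, size=(n, 2))
    return CountsDataset(
        counts=counts,
        coords=coords,
        gene_ids=[f"g{j}" for j in range(G)],
        spot_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)


@pytest.fixture(scope="session")
def sim_small():
    """A small spatial simulation shared by read-only tests."""
    cfg = SimConfig(n_genes=60, grid_rows=10, grid_cols=10, lengthscale=100.0,
                    null_fraction=0.5, seed=7)
    data, truth = simulate_dataset(cfg)
    return data, truth
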