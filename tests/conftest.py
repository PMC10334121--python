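import numpy as np
import pandas as pd
import pytest

from ffagg import SimulationConfig, build_nested_grid, simulate_dataset


@pytest.fixture(scope="session")
def small_grid():
    """64 x 64 km extent: 256 fine cells, 4 coarse blocks (2x2 rook lattice)."""
    return build_nested_grid((0, 0, 64, 64), fine_size=4, coarse_factor=8)


@pytest.fixture(scope="session")
def small_config():
    """A compact stated world for fast fitting tests: 400 cells, 4 blocks."""
    return SimulationConfig(
        extent=(0.0, 0.0, 80.0, 80.0),
        coarse_factor=10,
        coverage=0.25,
        seed=20,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def dense_car_logpdf(u, structure, mu=0.0, tau=1.0, gamma=0.0):
    """Independent oracle: dense multivariate-normal log-density with
    Sigma = (I - gamma C)^{-1} M / tau built explicitly."""
    from scipy import stats

    n = structure.n_blocks
    C = structure.C.toarray()
    M = np.diag(structure.M_diag)
    Sigma = np.linalg.inv(np.eye(n) - gamma * C) @ M / tau
    Sigma = 0.5 * (Sigma + Sigma.T)
    return stats.multivariate_normal(mean=np.full(n, mu) * np.ones(n), cov=Sigma).logpdf(u)


def random_connected_graph(n, rng, p_extra=0.15):
    """Random connected symmetric irreflexive adjacency on n nodes."""
    adj = {k: set() for k in range(n)}
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):  # spanning path keeps it connected
        adj[int(a)].add(int(b))
        adj[int(b)].add(int(a))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_extra:
                adj[i].add(j)
                adj[j].add(i)
    return {k: sorted(v) for k, v in adj.items()}


@pytest.fixture
def footprint_table():
    def make(grid, survey_id="S0", effort=2.0, cells=None):
        cells = grid.fine_cell_ids if cells is None else cells
        return pd.DataFrame(
            {"cell_id": cells, "survey_id": survey_id, "effort_km2": effort}
        )

    return make
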