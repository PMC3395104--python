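import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import somkit as sk

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def oils():
    return sk.gen_oils_like(seed=1)


@pytest.fixture(scope="session")
def saliva():
    return sk.gen_saliva_like(seed=1)


@pytest.fixture(scope="session")
def small_schedule():
    """A short schedule for tests that only need a reasonably organised map."""
    return sk.TrainingSchedule(T=1500, sigma0=3.0, sigmaT=0.5, alpha0=0.5, alphaT=0.01, seed=0)


def bfs_distances(grid: "sk.GridSpec") -> np.ndarray:
    """Independent oracle: hop counts over the odd-r neighbour graph.

    Neighbour offsets are written out per row parity (not derived from the
    package's cube-coordinate machinery) and distances come from
    breadth-first search.
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import shortest_path

    even = [(0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0)]
    odd = [(0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1)]
    n = grid.n_rows * grid.n_cols
    adj = lil_matrix((n, n))
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            for dr, dc in odd if r % 2 else even:
                rr, cc = r + dr, c + dc
                if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                    adj[r * grid.n_cols + c, rr * grid.n_cols + cc] = 1
    return shortest_path(adj.tocsr(), method="BF", unweighted=True)


def two_cluster_data(seed: int, n_per: int = 15, n_vars: int = 6, gap: float = 12.0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per, n_vars))
    b = rng.standard_normal((n_per, n_vars))
    b[:, 0] += gap
    X = np.vstack([a, b])
    labels = np.array(["a"] * n_per + ["b"] * n_per)
    return sk.Dataset(X), labels
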