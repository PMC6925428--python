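import numpy as np
import pytest

import fertimap as fm


@pytest.fixture(scope="session")
def small_city():
    """A 10x10 synthetic city shared by read-only tests."""
    return fm.simulate_city(10, 10, seed=2024)


@pytest.fixture(scope="session")
def lattice_4x5():
    return fm.generate_lattice(4, 5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 6) -> fm.AdjacencyGraph:
    """Random small connected graph: a spanning tree plus random extra edges."""
    n = int(rng.integers(2, max_nodes + 1))
    edges = {(int(min(i, j)), int(max(i, j)))
             for i, j in ((k, rng.integers(0, k)) for k in range(1, n))}
    extra = rng.integers(0, n)
    for _ in range(extra):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            edges.add((int(min(i, j)), int(max(i, j))))
    return fm.AdjacencyGraph(n=n, edges=np.array(sorted(edges)))
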