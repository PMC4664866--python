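import networkx as nx
import pytest

from netmend import load_karate_club


@pytest.fixture(scope="session")
def karate():
    return load_karate_club()


@pytest.fixture
def path3():
    """Path a-b-c."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


@pytest.fixture
def two_triangles():
    """Two disconnected triangles."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return g


def random_graph(seed, n_min=4, n_max=8, p=0.5):
    """A seeded Erdos-Renyi graph with at least one edge."""
    import numpy as np

    rng = np.random.default_rng(seed)
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() > 0:
            return g
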