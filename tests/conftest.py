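import networkx as nx
import numpy as np
import pytest

from diffdim import Graph


@pytest.fixture
def two_node_graph() -> Graph:
    return Graph.from_networkx(nx.Graph([(0, 1, {"weight": 1.0})]))


@pytest.fixture
def path3() -> Graph:
    return Graph.from_networkx(nx.path_graph(3))


@pytest.fixture
def star4() -> Graph:
    return Graph.from_networkx(nx.star_graph(3))  # hub + 3 leaves


def random_connected_graph(rng: np.random.Generator, n_max: int = 30) -> Graph:
    """Random connected weighted graph: spanning tree plus extra edges."""
    n = int(rng.integers(4, n_max + 1))
    g = nx.Graph()
    order = rng.permutation(n)
    for a, b in zip(order[:-1], order[1:]):
        g.add_edge(int(a), int(b), weight=float(rng.uniform(0.2, 3.0)))
    n_extra = int(rng.integers(1, n))
    for _ in range(n_extra):
        u, v = rng.integers(0, n, size=2)
        if u != v:
            g.add_edge(int(u), int(v), weight=float(rng.uniform(0.2, 3.0)))
    return Graph.from_networkx(g)
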