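import networkx as nx
import numpy as np
import pytest


def random_weighted_graph(rng: np.random.Generator, n_max: int = 8,
                          p: float = 0.4) -> nx.Graph:
    """Small random weighted graph for oracle-equivalence tests."""
    n = int(rng.integers(2, n_max + 1))
    G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    for u, v in G.edges():
        G[u][v]["weight"] = float(rng.uniform(0.5, 100.0))
    return G


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def path_graph():
    G = nx.Graph()
    G.add_edge("A", "B", weight=1.0)
    G.add_edge("B", "C", weight=1.0)
    return G


@pytest.fixture
def triangle_graph():
    G = nx.Graph()
    G.add_edge("A", "B", weight=2.0)
    G.add_edge("A", "C", weight=3.0)
    G.add_edge("B", "C", weight=5.0)
    return G


@pytest.fixture
def star_graph():
    """Center 'c' with 4 leaves, weights 2..5."""
    G = nx.Graph()
    for leaf, w in zip("wxyz", (2.0, 3.0, 4.0, 5.0)):
        G.add_edge("c", leaf, weight=w)
    return G
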