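import networkx as nx
import numpy as np
import pytest

from exponet import MetabolicNetwork


@pytest.fixture
def two_cliques_bridge() -> nx.Graph:
    """Two 4-cliques joined by a single bridge edge (13 edges total)."""
    g = nx.Graph()
    for base in ("a", "e"):
        nodes = [f"{base}{i}" for i in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(nodes[i], nodes[j])
    g.add_edge("a0", "e0")
    return g


@pytest.fixture
def toy_metabolic_network() -> MetabolicNetwork:
    """7-edge network holding a triangle {x,y,z} with degrees (3,2,2)."""
    g = nx.Graph()
    g.add_edges_from(
        [("x", "y"), ("y", "z"), ("z", "x"), ("x", "a"), ("a", "b"), ("b", "c"), ("c", "d")]
    )
    masses = {n: 100.0 + 10 * i for i, n in enumerate(sorted(g.nodes))}
    return MetabolicNetwork(graph=g, masses=masses)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
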