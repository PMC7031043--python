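import numpy as np
import networkx as nx
import pytest

from mediatornet import EdgeRecord, build_weighted_network


def weighted_graph(edges):
    """Build an analysis graph from (a, b, score) triples."""
    return build_weighted_network([EdgeRecord(a, b, s) for a, b, s in edges])


def random_weighted_graph(rng: np.random.Generator, n_nodes: int, edge_prob: float = 0.35):
    """Connected-ish random graph with scores in (0.2, 1]; may be disconnected."""
    names = [f"N{i}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                score = float(rng.uniform(0.2, 1.0))
                g.add_edge(names[i], names[j], score=score, weight=1.0 / score)
    return g


@pytest.fixture
def diamond():
    """Two equal-weight routes S-A-T and S-B-T."""
    return weighted_graph([("S", "A", 1.0), ("A", "T", 1.0), ("S", "B", 1.0), ("B", "T", 1.0)])


@pytest.fixture
def star_through_m():
    """S-M plus M-T1 and M-T2: M is the sole interior node on both routes."""
    return weighted_graph([("S", "M", 1.0), ("M", "T1", 1.0), ("M", "T2", 1.0)])


@pytest.fixture
def weighted_triangle():
    """Direct S-T edge (weight 3) loses to the two-hop route via A (weight 2)."""
    return weighted_graph([("S", "A", 1.0), ("A", "T", 1.0), ("S", "T", 1.0 / 3.0)])
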