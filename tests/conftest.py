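import networkx as nx
import numpy as np
import pytest

from pbmoo.expression import DESTable


def random_graph(n: int, m: int, seed: int) -> nx.Graph:
    """Seeded G(n, m) graph over string node labels."""
    rng = np.random.default_rng(seed)
    nodes = [f"N{i:02d}" for i in range(n)]
    pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
    m = min(m, len(pairs))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for idx in rng.choice(len(pairs), size=m, replace=False):
        g.add_edge(*pairs[idx])
    return g


def random_des(graph: nx.Graph, seed: int) -> DESTable:
    """Random DES values on a dyadic grid (k/1024) so path-cost sums are
    exact in binary floating point and tie-breaking is unambiguous."""
    rng = np.random.default_rng(seed)
    table = DESTable()
    for v in sorted(graph.nodes()):
        table.p_values[v] = [float(rng.integers(0, 1025)) / 1024.0]
    return table


@pytest.fixture
def triangle_square_graph() -> nx.Graph:
    """Triangle A-B-C plus square D-E-F-G joined at C-D."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C"),
                      ("C", "D"),
                      ("D", "E"), ("E", "F"), ("F", "G"), ("G", "D")])
    return g
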