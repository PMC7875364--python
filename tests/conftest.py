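import numpy as np
import pytest

from ctd.graph import DIFFUSION, WeightedGraph


def make_graph(names, edges, convention=DIFFUSION):
    """Build a graph from (u, v, w) triples."""
    names = tuple(names)
    idx = {n: i for i, n in enumerate(names)}
    adj = np.zeros((len(names), len(names)))
    for u, v, w in edges:
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = w
    return WeightedGraph(names, adj, convention)


def path_graph(n, prefix="n"):
    """Unit-weight path n0 - n1 - ... - n(n-1)."""
    names = [f"{prefix}{i:02d}" for i in range(n)]
    return make_graph(names, [(names[i], names[i + 1], 1.0) for i in range(n - 1)])


def complete_graph(n, prefix="n"):
    names = [f"{prefix}{i:02d}" for i in range(n)]
    return make_graph(
        names,
        [(names[i], names[j], 1.0) for i in range(n) for j in range(i + 1, n)],
    )


@pytest.fixture
def two_node_graph():
    return make_graph(["A", "B"], [("A", "B", 1.0)])


@pytest.fixture
def path_abcd():
    names = ["A", "B", "C", "D"]
    return make_graph(names, [(a, b, 1.0) for a, b in zip(names, names[1:])])
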