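import networkx as nx
import numpy as np
import pytest

from ulign import Alignment, Network


@pytest.fixture
def path_triangle():
    """A 3-node path aligned onto a triangle: c=2 conserved, 3 induced edges."""
    G1 = Network.from_edges("G1", [("a", "b"), ("b", "c")])
    G2 = Network.from_edges("G2", [("x", "y"), ("y", "z"), ("x", "z")])
    f = Alignment("G1", "G2", {"a": "x", "b": "y", "c": "z"})
    return G1, G2, f


def random_instance(rng, n_max=12, p=0.4):
    """A random small network pair with a random injective partial mapping."""
    n1 = int(rng.integers(2, n_max + 1))
    n2 = int(rng.integers(n1, n_max + 3))
    g1 = nx.gnp_random_graph(n1, p, seed=int(rng.integers(2**31)))
    g2 = nx.gnp_random_graph(n2, p, seed=int(rng.integers(2**31)))
    G1 = Network("G1", nx.relabel_nodes(g1, {i: f"s{i}" for i in range(n1)}))
    G2 = Network("G2", nx.relabel_nodes(g2, {i: f"t{i}" for i in range(n2)}))
    size = int(rng.integers(1, n1 + 1))
    sources = rng.choice(sorted(G1.nodes), size=size, replace=False)
    targets = rng.choice(sorted(G2.nodes), size=size, replace=False)
    f = Alignment("G1", "G2", {str(s): str(t) for s, t in zip(sources, targets)})
    return G1, G2, f


def brute_force_counts(G1, G2, f):
    """Conserved/induced edge counts by testing every node pair explicitly."""
    m = f.mapping
    conserved = 0
    nodes1 = sorted(G1.nodes)
    for i, u in enumerate(nodes1):
        for v in nodes1[i + 1 :]:
            if u in m and v in m and G1.has_edge(u, v) and G2.has_edge(m[u], m[v]):
                conserved += 1
    image = set(m.values())
    induced = 0
    nodes2 = sorted(G2.nodes)
    for i, x in enumerate(nodes2):
        for y in nodes2[i + 1 :]:
            if x in image and y in image and G2.has_edge(x, y):
                induced += 1
    return conserved, induced


@pytest.fixture
def rng():
    return np.random.default_rng(20170419)
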