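"""Topological quality scores of a global network alignment.

Given a pair of networks G1 (smaller, edge set E1) and G2 (larger, edge
set E2) and a one-to-one partial mapping f from V1 to V2, an edge (u,v)
of G1 is *conserved* when (f(u), f(v)) is an edge of G2.  With c the
number of conserved edges and i the number of G2 edges induced by the
image f(V1):

* NC  = |f| / |V1|                     (node coverage)
* EC  = c / |E1|                       (edge correctness)
* ICS = c / i                          (induced conserved sub-structure)
* S3  = c / (|E1| + i - c)             (symmetric sub-structure)
* LCC = largest connected component of the conserved subgraph, here
  normalised by |V1| so it is comparable across network pairs; the raw
  node and edge counts are exposed separately.

Scores with an empty denominator are *missing*, never zero: reporting 0
when G2 induces no edges at all would conflate "nothing to conserve"
with "nothing conserved" and bias averages downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .exceptions import UndefinedScoreError
from .net_io import Alignment, Network


@dataclass(frozen=True)
class ConservedSubgraph:
    """Edge-conservation counts underlying EC, ICS, S3 and LCC.

    ``conserved_edges`` live on G1's side: they are G1 edges whose image
    is a G2 edge.  ``induced_target_edge_count`` is the number of G2
    edges with both endpoints in the image of the alignment.
    """

    aligned_source_nodes: frozenset
    conserved_edges: frozenset  # of sorted 2-tuples
    induced_target_edge_count: int

    def __post_init__(self):
        for u, v in self.conserved_edges:
            if u not in self.aligned_source_nodes or v not in self.aligned_source_nodes:
                raise ValueError(f"conserved edge ({u},{v}) has an unaligned endpoint")
        if len(self.conserved_edges) > self.induced_target_edge_count:
            raise ValueError("more conserved edges than induced target edges")

    @property
    def n_conserved(self) -> int:
        return len(self.conserved_edges)


@dataclass(frozen=True)
class TopoScores:
    """The five topological scores; missing values are None."""

    nc: float
    ec: float | None
    ics: float | None
    s3: float | None
    lcc: float
    lcc_nodes: int = 0
    lcc_edges: int = 0


def conserved_subgraph(G1: Network, G2: Network, f: Alignment) -> ConservedSubgraph:
    """Count conserved and induced edges for alignment ``f`` of G1 into G2."""
    m = f.mapping
    conserved = frozenset(
        tuple(sorted((u, v)))
        for u, v in G1.graph.edges
        if u in m and v in m and G2.graph.has_edge(m[u], m[v])
    )
    image = set(m.values())
    induced = G2.graph.subgraph(image).number_of_edges()
    return ConservedSubgraph(frozenset(m), conserved, induced)


def node_coverage(G1: Network, f: Alignment) -> float:
    """Fraction of smaller-network nodes that the alignment maps."""
    return len(f.mapping) / G1.n_nodes


def edge_correctness(cs: ConservedSubgraph, G1: Network) -> float:
    if G1.n_edges == 0:
        raise UndefinedScoreError("EC undefined: smaller network has no edges")
    return cs.n_conserved / G1.n_edges


def induced_conserved_structure(cs: ConservedSubgraph) -> float:
    if cs.induced_target_edge_count == 0:
        raise UndefinedScoreError("ICS undefined: image induces no edges")
    return cs.n_conserved / cs.induced_target_edge_count


def symmetric_substructure(cs: ConservedSubgraph, G1: Network) -> float:
    denom = G1.n_edges + cs.induced_target_edge_count - cs.n_conserved
    if denom == 0:
        raise UndefinedScoreError("S3 undefined: no edges on either side")
    return cs.n_conserved / denom


def largest_component_counts(cs: ConservedSubgraph) -> tuple[int, int]:
    """(node count, edge count) of the largest conserved connected component.

    Built on G1's side from the conserved edges; the image of the
    component in G2 is isomorphic by construction, so the side does not
    change the value.  Returns (0, 0) when no edge is conserved.
    """
    if not cs.conserved_edges:
        return (0, 0)
    g = nx.Graph()
    g.add_edges_from(cs.conserved_edges)
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    return (sub.number_of_nodes(), sub.number_of_edges())


def largest_conserved_component(cs: ConservedSubgraph, G1: Network) -> float:
    """Node count of the largest conserved component over |V1| (0 if none)."""
    n, _ = largest_component_counts(cs)
    return n / G1.n_nodes


def topo_scores(G1: Network, G2: Network, f: Alignment) -> TopoScores:
    """All five topological scores at once; undefined ones come back None."""
    cs = conserved_subgraph(G1, G2, f)

    def _maybe(fn, *args):
        try:
            return fn(*args)
        except UndefinedScoreError:
            return None

    n, m = largest_component_counts(cs)
    return TopoScores(
        nc=node_coverage(G1, f),
        ec=_maybe(edge_correctness, cs, G1),
        ics=_maybe(induced_conserved_structure, cs),
        s3=_maybe(symmetric_substructure, cs, G1),
        lcc=n / G1.n_nodes,
        lcc_nodes=n,
        lcc_edges=m,
    )
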