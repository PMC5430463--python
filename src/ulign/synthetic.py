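"""Synthetic network pairs, planted alignments and annotations.

Test fixtures only — synthetic graphs are not a model of PPI evolution
and real aligner benchmarking should use real interactomes.  The
generators provide what the rest of the package needs to be exercised
without downloads: a pair of networks of unequal size with a known
("planted") correspondence, corrupted versions of that correspondence
with a tunable fraction of wrong mappings, and annotation tables whose
functional coherence along the planted mapping is tunable.

The default construction duplicates the smaller network inside the
larger one: G2 starts as a relabelled copy of G1, grows extra nodes by
preferential attachment and has a fraction of its edges rewired.  This
yields genuine conserved structure for the planted mapping, unlike two
independent Erdős–Rényi draws (kept available as a null model).

All randomness flows from the single integer seed of the spec; the same
spec always produces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .net_io import Alignment, AnnotationSet, Network


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic instance.

    n1, n2:
        Node counts of the smaller and larger network (n1 <= n2).
    model:
        ``"duplication"`` (G2 grown from a copy of G1) or
        ``"erdos-renyi"`` (independent G(n, p) pair, null model).
    edge_density:
        Edge probability of the G(n1, p) base graph.
    attach_edges:
        Edges each added node brings under preferential attachment.
    rewire_fraction:
        Fraction of G2's copied edges rewired to random non-edges.
    shuffle_fraction:
        Fraction of planted mappings re-targeted by
        :func:`corrupt_alignment` when driven from the spec.
    n_terms, coherence:
        Annotation vocabulary size and the probability that a planted
        pair is given a shared term.
    seed:
        Single integer driving every generator stream.
    """

    n1: int = 50
    n2: int = 80
    model: str = "duplication"
    edge_density: float = 0.08
    attach_edges: int = 3
    rewire_fraction: float = 0.1
    shuffle_fraction: float = 0.0
    n_terms: int = 20
    coherence: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.n1 <= self.n2):
            raise ValueError(f"need 1 <= n1 <= n2, got n1={self.n1}, n2={self.n2}")
        for name in ("edge_density", "rewire_fraction", "shuffle_fraction", "coherence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.model not in ("duplication", "erdos-renyi"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")


def _src(i: int) -> str:
    return f"s{i:04d}"


def _tgt(i: int) -> str:
    return f"t{i:04d}"


def make_network_pair(spec: SyntheticSpec) -> tuple[Network, Network, Alignment]:
    """Generate (G1, G2, planted alignment) from a spec.

    The planted alignment maps every G1 node onto its copy in G2; with
    no perturbation it conserves every edge (EC = ICS = S3 = 1).
    """
    rng = np.random.default_rng(spec.seed)
    g1 = nx.gnp_random_graph(spec.n1, spec.edge_density, seed=int(rng.integers(2**31)))
    if g1.number_of_edges() == 0:
        raise ValueError("edge density too low: base graph has no edges")
    g1 = nx.relabel_nodes(g1, {i: _src(i) for i in range(spec.n1)})

    if spec.model == "erdos-renyi":
        g2 = nx.gnp_random_graph(
            spec.n2, spec.edge_density, seed=int(rng.integers(2**31))
        )
        g2 = nx.relabel_nodes(g2, {i: _tgt(i) for i in range(spec.n2)})
    else:
        g2 = nx.relabel_nodes(g1, {_src(i): _tgt(i) for i in range(spec.n1)})
        # grow extra nodes, attaching preferentially to high-degree nodes
        for i in range(spec.n1, spec.n2):
            existing = sorted(g2.nodes)
            deg = np.array([g2.degree(u) + 1 for u in existing], dtype=float)
            k = min(spec.attach_edges, len(existing))
            targets = rng.choice(existing, size=k, replace=False, p=deg / deg.sum())
            new = _tgt(i)
            g2.add_node(new)
            for t in targets:
                g2.add_edge(new, t)
        # rewire a fraction of the copied edges
        copied = sorted(
            tuple(sorted(e)) for e in g2.edges if e[0] < _tgt(spec.n1) and e[1] < _tgt(spec.n1)
        )
        n_rewire = int(round(spec.rewire_fraction * len(copied)))
        if n_rewire:
            idx = rng.choice(len(copied), size=n_rewire, replace=False)
            nodes = sorted(g2.nodes)
            for j in idx:
                u, v = copied[j]
                if not g2.has_edge(u, v):
                    continue
                g2.remove_edge(u, v)
                for _ in range(50):  # rejection-sample a non-edge
                    a, b = rng.choice(nodes, size=2, replace=False)
                    if not g2.has_edge(a, b):
                        g2.add_edge(a, b)
                        break
                else:
                    g2.add_edge(u, v)  # dense graph: keep the original edge

    G1 = Network("G1", g1)
    G2 = Network("G2", g2)
    planted = Alignment(
        "G1", "G2", {_src(i): _tgt(i) for i in range(spec.n1)}, aligner="planted"
    )
    return G1, G2, planted


def corrupt_alignment(
    planted: Alignment, target: Network, shuffle_fraction: float, seed: int
) -> Alignment:
    """Re-target a fraction of mapping pairs to unused target nodes.

    The chosen pairs get distinct targets drawn uniformly from the
    target nodes not used by the planted alignment, so injectivity is
    preserved and a re-targeted pair is guaranteed wrong.
    """
    if not (0.0 <= shuffle_fraction <= 1.0):
        raise ValueError(f"shuffle_fraction must be in [0, 1], got {shuffle_fraction}")
    rng = np.random.default_rng(seed)
    sources = sorted(planted.mapping)
    n_move = int(round(shuffle_fraction * len(sources)))
    if n_move == 0:
        return replace(planted, aligner=planted.aligner, alpha=planted.alpha)
    unused = sorted(target.nodes - planted.image())
    if len(unused) < n_move:
        raise ValueError(
            f"cannot re-target {n_move} pairs: only {len(unused)} unused targets"
        )
    moved = rng.choice(sources, size=n_move, replace=False)
    new_targets = rng.choice(unused, size=n_move, replace=False)
    mapping = dict(planted.mapping)
    for s, t in zip(moved, new_targets):
        mapping[str(s)] = str(t)
    return Alignment(
        planted.source_net,
        planted.target_net,
        mapping,
        aligner=planted.aligner,
        alpha=planted.alpha,
    )


def make_annotations(
    G1: Network,
    G2: Network,
    planted: Alignment,
    n_terms: int = 20,
    coherence: float = 0.8,
    seed: int = 0,
    namespace: str = "KEGG",
) -> tuple[AnnotationSet, AnnotationSet]:
    """Annotation tables whose coherence along the planted mapping is tunable.

    Every protein in both networks receives one random term; each
    planted pair additionally shares a common random term with
    probability ``coherence``.  With coherence 1 the planted alignment
    therefore reaches an annotation-overlap score of 1, and with
    coherence 0 overlaps occur only by chance.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if not (0.0 <= coherence <= 1.0):
        raise ValueError(f"coherence must be in [0, 1], got {coherence}")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:03d}" for i in range(n_terms)]
    ann1: dict[str, set] = {u: {terms[rng.integers(n_terms)]} for u in sorted(G1.nodes)}
    ann2: dict[str, set] = {v: {terms[rng.integers(n_terms)]} for v in sorted(G2.nodes)}
    for u in sorted(planted.mapping):
        if rng.random() < coherence:
            shared = terms[rng.integers(n_terms)]
            ann1[u].add(shared)
            ann2[planted.mapping[u]].add(shared)
    return (
        AnnotationSet(namespace, {p: frozenset(t) for p, t in ann1.items()}),
        AnnotationSet(namespace, {p: frozenset(t) for p, t in ann2.items()}),
    )
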