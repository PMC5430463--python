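"""Reading, writing and validating networks, alignments and annotations.

PPI networks are undirected simple graphs over case-sensitive protein
identifiers.  Alignments are injective partial mappings from the nodes of
the smaller network of a pair to the nodes of the larger one.  Annotation
sets map proteins to flat term identifiers (KEGG pathways or GO terms in
one aspect); no ontology-graph propagation is ever applied.

File dialects
-------------
* networks: whitespace/tab-separated edge lists, first two tokens per line,
  ``#`` comment lines ignored; a single-token line declares an isolated
  node (needed for lossless round trips).  An optional LEDA ``.gw`` reader
  covers GRAAL-family inputs.
* alignments: two-column TSV, source (smaller-network) node first.
* annotations: two-column (protein, term) TSV or GMT
  (term, description, member proteins).
* unified mappings: four-column TSV
  (source, target, support_count, comma-joined contributing labels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .exceptions import MappingError, ParseError

logger = logging.getLogger(__name__)

#: Annotation namespaces with a conventional meaning.
NAMESPACES = ("KEGG", "GO-BP", "GO-MF", "GO-CC")


class Network:
    """An undirected simple graph over string protein identifiers.

    Parameters
    ----------
    name:
        Label of the network (e.g. the species).
    graph:
        A :class:`networkx.Graph`; must be simple (no self-loops) and
        non-empty.  The graph is used as-is, not copied.
    """

    __slots__ = ("name", "graph")

    def __init__(self, name: str, graph: nx.Graph):
        if graph.number_of_nodes() < 1:
            raise ValueError(f"network {name!r} has no nodes")
        loops = list(nx.selfloop_edges(graph))
        if loops:
            raise ValueError(f"network {name!r} contains self-loops: {loops[:3]}")
        self.name = name
        self.graph = graph

    @classmethod
    def from_edges(
        cls, name: str, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
    ) -> "Network":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return cls(name, g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self.name == other.name
            and self.nodes == other.nodes
            and self.edge_set() == other.edge_set()
        )

    def __repr__(self) -> str:
        return f"Network({self.name!r}, n={self.n_nodes}, m={self.n_edges})"


@dataclass(frozen=True)
class Alignment:
    """A one-to-one partial node mapping between two networks.

    ``mapping`` sends nodes of the smaller (source) network to nodes of
    the larger (target) network; both sides must be duplicate-free.
    ``aligner`` and ``alpha`` record which program produced the alignment
    and at which topology/sequence balancing parameter.
    """

    source_net: str
    target_net: str
    mapping: Mapping[str, str]
    aligner: str | None = None
    alpha: float | None = None

    def __post_init__(self):
        targets = set(self.mapping.values())
        if len(targets) != len(self.mapping):
            seen: set[str] = set()
            for t in self.mapping.values():
                if t in seen:
                    raise MappingError(f"target node {t!r} mapped more than once")
                seen.add(t)
        if self.alpha is not None and not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def label(self) -> str:
        if self.aligner is None:
            return "alignment"
        if self.alpha is None:
            return self.aligner
        return f"{self.aligner}@{self.alpha:g}"

    def image(self) -> set[str]:
        """Target-side node set used by this alignment."""
        return set(self.mapping.values())

    def sources(self) -> set[str]:
        return set(self.mapping)

    def inverted(self) -> "Alignment":
        """Swap source and target roles (valid because mappings are 1-1)."""
        return Alignment(
            source_net=self.target_net,
            target_net=self.source_net,
            mapping={v: k for k, v in self.mapping.items()},
            aligner=self.aligner,
            alpha=self.alpha,
        )


@dataclass(frozen=True)
class AnnotationSet:
    """Protein -> set of term identifiers within one namespace."""

    namespace: str
    annotations: Mapping[str, frozenset]

    def __post_init__(self):
        for p, terms in self.annotations.items():
            if not terms:
                raise ValueError(f"protein {p!r} has an empty term set")

    def terms_of(self, protein: str) -> frozenset:
        return self.annotations.get(protein, frozenset())

    def annotated_within(self, nodes: Iterable[str]) -> set[str]:
        """Annotated proteins that are nodes of the given network."""
        node_set = set(nodes)
        return {p for p in self.annotations if p in node_set}

    def __len__(self) -> int:
        return len(self.annotations)


@dataclass(frozen=True)
class UnifiedMapping:
    """Many-to-many union of one-to-one alignments with provenance.

    ``support`` maps each (source, target) pair to the tuple of labels of
    the alignments that contributed it.  Unlike :class:`Alignment`, a
    source node may map to several targets and vice versa.
    """

    source_net: str
    target_net: str
    support: Mapping[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for pair, labels in self.support.items():
            if not labels:
                raise ValueError(f"pair {pair} has no contributing alignment")

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.support)

    def __len__(self) -> int:
        return len(self.support)


# ---------------------------------------------------------------------------
# orientation helpers

def smaller_larger(a: Network, b: Network) -> tuple[Network, Network]:
    """Order a network pair canonically: fewer nodes first, ties broken by
    edge count, then by name."""
    ka = (a.n_nodes, a.n_edges, a.name)
    kb = (b.n_nodes, b.n_edges, b.name)
    return (a, b) if ka <= kb else (b, a)


def canonical_alignment(aln: Alignment, net1: Network, net2: Network) -> Alignment:
    """Re-orient an alignment so its source is the smaller network of the pair."""
    small, large = smaller_larger(net1, net2)
    if aln.source_net == small.name and aln.target_net == large.name:
        return aln
    if aln.source_net == large.name and aln.target_net == small.name:
        return aln.inverted()
    raise ValueError(
        f"alignment relates {aln.source_net!r}->{aln.target_net!r}, "
        f"not the pair ({net1.name!r}, {net2.name!r})"
    )


# ---------------------------------------------------------------------------
# networks

def read_network(path, name: str | None = None, format: str | None = None) -> Network:
    """Read a network from an edge list or LEDA ``.gw`` file.

    Self-loops and duplicate edges are dropped, each with a logged warning
    carrying a count.  ``format`` is ``"tsv-edgelist"`` or ``"leda-gw"``;
    by default it is inferred from the ``.gw`` extension.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    if format is None:
        format = "leda-gw" if path.suffix == ".gw" else "tsv-edgelist"
    if format == "leda-gw":
        return _read_leda(path, name)
    if format != "tsv-edgelist":
        raise ValueError(f"unknown network format {format!r}")

    g = nx.Graph()
    n_loops = 0
    n_dups = 0
    any_line = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            any_line = True
            tokens = line.split()
            if len(tokens) == 1:
                g.add_node(tokens[0])
                continue
            u, v = tokens[0], tokens[1]
            if u == v:
                n_loops += 1
                continue
            if g.has_edge(u, v):
                n_dups += 1
                continue
            g.add_edge(u, v)
    if not any_line:
        raise ParseError("empty network file", path=path)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    if n_dups:
        logger.warning("%s: dropped %d duplicate edge(s)", path, n_dups)
    return Network(name, g)


def _read_leda(path: Path, name: str) -> Network:
    """Minimal LEDA .gw reader: header, node section, edge section."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not body or body[0].strip() != "LEDA.GRAPH":
        raise ParseError("missing LEDA.GRAPH header", path=path, line=1)
    # two type lines and a directedness flag (-1/-2) precede the node count
    idx = 3
    try:
        while body[idx].strip().startswith("-") or not body[idx].strip().isdigit():
            idx += 1
        n = int(body[idx].strip())
        labels = []
        for i in range(n):
            ln = body[idx + 1 + i].strip()
            if not (ln.startswith("|{") and ln.endswith("}|")):
                raise ParseError(f"bad node line {ln!r}", path=path)
            labels.append(ln[2:-2])
        g = nx.Graph()
        g.add_nodes_from(labels)
        eidx = idx + 1 + n
        m = int(body[eidx].strip())
        n_loops = n_dups = 0
        for i in range(m):
            tokens = body[eidx + 1 + i].split()
            u = labels[int(tokens[0]) - 1]
            v = labels[int(tokens[1]) - 1]
            if u == v:
                n_loops += 1
                continue
            if g.has_edge(u, v):
                n_dups += 1
                continue
            g.add_edge(u, v)
    except (IndexError, ValueError) as exc:
        raise ParseError(f"truncated or malformed LEDA file: {exc}", path=path) from exc
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    if n_dups:
        logger.warning("%s: dropped %d duplicate edge(s)", path, n_dups)
    return Network(name, g)


def write_network(net: Network, path) -> None:
    """Write a network as an edge list; isolated nodes get their own line."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")
        for u in sorted(n for n in net.graph.nodes if net.graph.degree(n) == 0):
            fh.write(f"{u}\n")


# ---------------------------------------------------------------------------
# alignments

def read_alignment(
    path,
    source: Network,
    target: Network,
    aligner: str | None = None,
    alpha: float | None = None,
) -> Alignment:
    """Read a two-column TSV alignment and validate all cross-references.

    Duplicate source or target nodes raise :class:`MappingError` naming the
    offending node; rows referencing nodes absent from either network raise
    :class:`MappingError` as well.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    used_targets: set[str] = set()
    src_nodes = source.nodes
    tgt_nodes = target.nodes
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError("expected two columns", path=path, line=lineno)
            u, v = tokens[0], tokens[1]
            if u not in src_nodes:
                raise MappingError(
                    f"{path}:{lineno}: source node {u!r} not in network {source.name!r}"
                )
            if v not in tgt_nodes:
                raise MappingError(
                    f"{path}:{lineno}: target node {v!r} not in network {target.name!r}"
                )
            if u in mapping:
                raise MappingError(f"{path}:{lineno}: duplicate source node {u!r}")
            if v in used_targets:
                raise MappingError(f"{path}:{lineno}: duplicate target node {v!r}")
            mapping[u] = v
            used_targets.add(v)
    return Alignment(source.name, target.name, mapping, aligner=aligner, alpha=alpha)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(aln.mapping.items()):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# annotations

def read_annotations(path, namespace: str, format: str | None = None) -> AnnotationSet:
    """Read (protein, term) TSV pairs or a GMT file into an AnnotationSet.

    Duplicate (protein, term) rows collapse silently.
    """
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix == ".gmt" else "tsv-pairs"
    ann: dict[str, set] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if format == "tsv-pairs":
                tokens = line.split("\t") if "\t" in line else line.split()
                if len(tokens) < 2 or not tokens[0].strip() or not tokens[1].strip():
                    raise ParseError(
                        "expected non-empty protein and term fields",
                        path=path,
                        line=lineno,
                    )
                ann.setdefault(tokens[0].strip(), set()).add(tokens[1].strip())
            elif format == "gmt":
                tokens = line.split("\t")
                if len(tokens) < 3 or not tokens[0].strip():
                    raise ParseError(
                        "GMT line needs term, description and >= 1 member",
                        path=path,
                        line=lineno,
                    )
                term = tokens[0].strip()
                for member in tokens[2:]:
                    member = member.strip()
                    if member:
                        ann.setdefault(member, set()).add(term)
            else:
                raise ValueError(f"unknown annotation format {format!r}")
    return AnnotationSet(namespace, {p: frozenset(t) for p, t in ann.items()})


def write_annotations(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for p in sorted(ann.annotations):
            for t in sorted(ann.annotations[p]):
                fh.write(f"{p}\t{t}\n")


# ---------------------------------------------------------------------------
# unified mappings

def read_unified(path, source_net: str = "", target_net: str = "") -> UnifiedMapping:
    """Read a four-column unified-mapping TSV."""
    path = Path(path)
    support: dict[tuple[str, str], tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) < 4:
                raise ParseError("expected four columns", path=path, line=lineno)
            s, t, count, labels = tokens[0], tokens[1], tokens[2], tokens[3]
            label_tuple = tuple(x for x in labels.split(",") if x)
            if len(label_tuple) != int(count):
                raise ParseError(
                    f"support count {count} does not match labels {labels!r}",
                    path=path,
                    line=lineno,
                )
            support[(s, t)] = label_tuple
    return UnifiedMapping(source_net, target_net, support)


def write_unified(u: UnifiedMapping, path) -> None:
    with open(path, "w") as fh:
        for (s, t) in sorted(u.support):
            labels = u.support[(s, t)]
            fh.write(f"{s}\t{t}\t{len(labels)}\t{','.join(labels)}\n")
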