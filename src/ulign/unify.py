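"""Union of one-to-one alignments into a many-to-many mapping.

Individual global aligners leave much of the larger network unaligned
(at best |V1|/|V2| of it can be covered by a single one-to-one
alignment), but different aligners use different regions of the larger
network.  Taking the union of their alignments yields a many-to-many
mapping that can cover both networks almost entirely.  The union is no
longer one-to-one, so it cannot be scored with the usual alignment
measures; instead its multiple mappings define a soft (overlapping)
clustering of the smaller network's proteins — one cluster per larger-
network protein, containing all smaller-network proteins mapped to it —
whose biological relevance is assessed by enrichment analysis and by the
consistency of annotation transfer.
"""

from __future__ import annotations

from typing import Sequence

from dataclasses import dataclass

from .exceptions import UndefinedScoreError
from .net_io import Alignment, AnnotationSet, Network, UnifiedMapping


@dataclass(frozen=True)
class SoftClustering:
    """Target protein -> set of source proteins collectively mapped to it."""

    clusters: dict

    def __post_init__(self):
        for t, members in self.clusters.items():
            if not members:
                raise ValueError(f"cluster {t!r} is empty")

    def as_pairs(self) -> set[tuple[str, str]]:
        """Flatten back to (source, target) pairs."""
        return {(s, t) for t, members in self.clusters.items() for s in members}

    def __len__(self) -> int:
        return len(self.clusters)


def unify(
    alignments: Sequence[Alignment], labels: Sequence[str] | None = None
) -> UnifiedMapping:
    """Union the mappings of several alignments, recording per-pair provenance.

    All alignments must relate the same canonically oriented network
    pair.  Duplicate pairs are merged; their support lists every
    contributing alignment's label.
    """
    if not alignments:
        raise ValueError("need at least one alignment")
    if labels is None:
        labels = [a.label for a in alignments]
    if len(labels) != len(alignments):
        raise ValueError("labels and alignments differ in length")
    first = alignments[0]
    support: dict[tuple[str, str], list[str]] = {}
    for aln, lab in zip(alignments, labels):
        if (aln.source_net, aln.target_net) == (first.target_net, first.source_net):
            aln = aln.inverted()
        if (aln.source_net, aln.target_net) != (first.source_net, first.target_net):
            raise ValueError(
                f"alignment {lab!r} relates ({aln.source_net}, {aln.target_net}), "
                f"expected ({first.source_net}, {first.target_net})"
            )
        for u, v in aln.mapping.items():
            support.setdefault((u, v), []).append(lab)
    return UnifiedMapping(
        first.source_net,
        first.target_net,
        {pair: tuple(labs) for pair, labs in support.items()},
    )


def coverage_curve(
    alignments: Sequence[Alignment], network: Network, side: str = "target"
) -> list[float]:
    """Cumulative node coverage of one network by the first k alignments.

    Entry k (k = 0..n) is the fraction of ``network``'s nodes used, on
    the chosen side, by the union of the first k alignments; entry 0 is
    0 (no alignment).  The caller fixes the order, conventionally best
    aligner first.
    """
    if side not in ("source", "target"):
        raise ValueError("side must be 'source' or 'target'")
    covered: set[str] = set()
    curve = [0.0]
    for aln in alignments:
        covered |= aln.sources() if side == "source" else aln.image()
        curve.append(len(covered) / network.n_nodes)
    return curve


def soft_clusters(u: UnifiedMapping) -> SoftClustering:
    """Group source proteins mapped to the same target protein."""
    if len(u) == 0:
        raise ValueError("empty unified mapping")
    clusters: dict[str, set] = {}
    for s, t in u.pairs:
        clusters.setdefault(t, set()).add(s)
    return SoftClustering({t: frozenset(m) for t, m in clusters.items()})


def transfer_consistency(
    clusters: SoftClustering, ann_src: AnnotationSet, ann_tgt: AnnotationSet
) -> float:
    """Fraction of annotated targets sharing a term with their source cluster.

    Only clusters whose target protein is annotated enter the
    denominator; a cluster is consistent when the union of its members'
    annotations intersects the target's annotations.
    """
    if ann_src.namespace != ann_tgt.namespace:
        raise ValueError(
            f"namespace mismatch: {ann_src.namespace!r} vs {ann_tgt.namespace!r}"
        )
    eligible = [t for t in clusters.clusters if ann_tgt.terms_of(t)]
    if not eligible:
        raise UndefinedScoreError("no cluster has an annotated target protein")
    consistent = 0
    for t in eligible:
        pooled: set = set()
        for s in clusters.clusters[t]:
            pooled |= ann_src.terms_of(s)
        if pooled & ann_tgt.terms_of(t):
            consistent += 1
    return consistent / len(eligible)
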