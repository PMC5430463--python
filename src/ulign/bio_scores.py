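"""Annotation-overlap (biological coherence) scores.

A mapped pair (u, v) is *functionally similar* when u and v share at
least one annotation term — a common KEGG pathway for the KP score, or a
common GO term within one aspect for GO-BP / GO-MF / GO-CC.  The score
is the number of functionally similar mapped pairs divided by the
smaller of the two networks' annotated-protein counts.

The denominator deliberately counts annotated proteins per network, not
annotated mapped pairs: an aligner that leaves annotated proteins
unmapped is penalised.  Annotations of proteins that are not nodes of
the respective network are ignored.  Terms match by exact identifier
equality; no GO-hierarchy propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import UndefinedScoreError
from .net_io import Alignment, AnnotationSet, Network


@dataclass(frozen=True)
class BioScore:
    namespace: str
    value: float
    shared_pairs: int
    denominator: int


def annotation_overlap_score(
    f: Alignment,
    ann_source: AnnotationSet,
    ann_target: AnnotationSet,
    source_net: Network | None = None,
    target_net: Network | None = None,
) -> BioScore:
    """Fraction of mapped pairs sharing a term, over the smaller annotated count.

    When the networks are given, only annotations of their nodes count;
    otherwise the full annotation tables define the annotated sets.
    Raises :class:`UndefinedScoreError` when either network has no
    annotated protein.
    """
    if ann_source.namespace != ann_target.namespace:
        raise ValueError(
            f"namespace mismatch: {ann_source.namespace!r} vs {ann_target.namespace!r}"
        )
    if source_net is not None:
        src_annotated = ann_source.annotated_within(source_net.nodes)
    else:
        src_annotated = set(ann_source.annotations)
    if target_net is not None:
        tgt_annotated = ann_target.annotated_within(target_net.nodes)
    else:
        tgt_annotated = set(ann_target.annotations)

    denominator = min(len(src_annotated), len(tgt_annotated))
    if denominator == 0:
        raise UndefinedScoreError(
            f"{ann_source.namespace} score undefined: a network has no annotated protein"
        )
    shared = sum(
        1
        for u, v in f.mapping.items()
        if u in src_annotated
        and v in tgt_annotated
        and ann_source.annotations[u] & ann_target.annotations[v]
    )
    return BioScore(ann_source.namespace, shared / denominator, shared, denominator)
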