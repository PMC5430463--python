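"""Convenience layer: all nine scores of one alignment in one call."""

from __future__ import annotations

import math
from typing import Mapping

from .bio_scores import annotation_overlap_score
from .exceptions import UndefinedScoreError
from .net_io import Alignment, AnnotationSet, Network, canonical_alignment, smaller_larger
from .topo_scores import topo_scores


def score_alignment(
    net_a: Network,
    net_b: Network,
    aln: Alignment,
    annotations: Mapping[str, tuple[AnnotationSet, AnnotationSet]] | None = None,
) -> dict[str, float | None]:
    """NC/EC/ICS/S3/LCC plus one annotation-overlap score per namespace.

    The pair is oriented canonically (smaller network as source) before
    scoring, so the caller may pass the networks in either order.
    ``annotations`` maps a namespace (e.g. ``"KP"``, ``"GO-BP"``) to the
    (source annotations, target annotations) tables, given in the same
    orientation as ``net_a``/``net_b``.  Undefined scores are None.
    """
    small, large = smaller_larger(net_a, net_b)
    aln = canonical_alignment(aln, net_a, net_b)
    flipped = small.name != net_a.name

    ts = topo_scores(small, large, aln)
    row: dict[str, float | None] = {
        "NC": ts.nc,
        "EC": ts.ec,
        "ICS": ts.ics,
        "S3": ts.s3,
        "LCC": ts.lcc,
    }
    for ns, (ann_a, ann_b) in (annotations or {}).items():
        ann_src, ann_tgt = (ann_b, ann_a) if flipped else (ann_a, ann_b)
        try:
            row[ns] = annotation_overlap_score(aln, ann_src, ann_tgt, small, large).value
        except UndefinedScoreError:
            row[ns] = None
    return row


def format_score(value: float | None, digits: int = 6) -> str:
    """Render a score for TSV output; missing values become ``NA``."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "NA"
    return f"{value:.{digits}g}"
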