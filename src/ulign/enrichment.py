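"""Hypergeometric enrichment of soft clusters with BH correction.

Each cluster with at least two annotated members is tested, term by
term, against a background universe of annotated proteins: with N the
universe size, K the background proteins carrying the term, n the
annotated cluster members and k of them carrying the term, the raw
p-value is the upper tail P(X >= k) of a hypergeometric(N, K, n)
variable — sampling without replacement.  Benjamini-Hochberg step-up
correction is applied within each cluster's family of term tests by
default (per-cluster scope matches asking, cluster by cluster, whether
at least one term survives); a global family across all clusters is
available as an alternative scope.

Unannotated cluster members carry no information under sampling from
the annotated universe and are ignored; only terms carried by at least
one member are tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import UndefinedScoreError
from .net_io import AnnotationSet
from .unify import SoftClustering


@dataclass(frozen=True)
class EnrichmentResult:
    cluster_id: str
    term: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adj: float


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ hypergeometric(N, K, n).

    N: population size, K: successes in the population, n: draws without
    replacement, k: observed successes among the draws.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(
            f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k); scipy computes this stably
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotone
    non-decreasing from the largest down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def cluster_enrichment(
    clusters: SoftClustering,
    ann: AnnotationSet,
    alpha: float = 0.05,
    background: Iterable[str] | None = None,
    bh_scope: str = "cluster",
) -> tuple[list[EnrichmentResult], float]:
    """Term enrichment of every eligible cluster, plus the significant fraction.

    Parameters
    ----------
    clusters:
        Soft clustering of source-network proteins.
    ann:
        Annotations of the source-network proteins.
    alpha:
        Significance level on the adjusted p-values (default 0.05).
    background:
        Proteins defining the universe; the universe is the annotated
        subset of it.  Defaults to every annotated protein in ``ann``
        (pass the source network's node set to restrict to one network).
    bh_scope:
        ``"cluster"`` corrects within each cluster's term family,
        ``"global"`` across all (cluster, term) tests.

    Returns
    -------
    (results, fraction):
        One :class:`EnrichmentResult` per tested (cluster, term), and
        the fraction of eligible clusters (>= 2 annotated members) with
        at least one term at ``p_adj <= alpha``.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if bh_scope not in ("cluster", "global"):
        raise ValueError("bh_scope must be 'cluster' or 'global'")

    if background is None:
        universe = set(ann.annotations)
    else:
        universe = ann.annotated_within(background)
    N = len(universe)

    term_counts: dict[str, int] = {}
    for p in universe:
        for t in ann.annotations[p]:
            term_counts[t] = term_counts.get(t, 0) + 1

    eligible: list[tuple[str, list[str]]] = []
    for cid, members in clusters.clusters.items():
        annotated = sorted(m for m in members if m in universe)
        if len(annotated) >= 2:
            eligible.append((cid, annotated))
    if not eligible:
        raise UndefinedScoreError("no cluster has at least two annotated members")

    raw: list[EnrichmentResult] = []
    for cid, annotated in eligible:
        n = len(annotated)
        terms = sorted({t for m in annotated for t in ann.annotations[m]})
        for term in terms:
            k = sum(1 for m in annotated if term in ann.annotations[m])
            K = term_counts[term]
            p_raw = hypergeom_upper_tail(k, K, n, N)
            raw.append(EnrichmentResult(cid, term, k, n, K, N, p_raw, p_raw))

    results: list[EnrichmentResult] = []
    if bh_scope == "global":
        adj = bh_adjust([r.p_raw for r in raw])
        results = [
            EnrichmentResult(r.cluster_id, r.term, r.k, r.n, r.K, r.N, r.p_raw, a)
            for r, a in zip(raw, adj)
        ]
    else:
        by_cluster: dict[str, list[EnrichmentResult]] = {}
        for r in raw:
            by_cluster.setdefault(r.cluster_id, []).append(r)
        for cid, rows in by_cluster.items():
            adj = bh_adjust([r.p_raw for r in rows])
            results.extend(
                EnrichmentResult(r.cluster_id, r.term, r.k, r.n, r.K, r.N, r.p_raw, a)
                for r, a in zip(rows, adj)
            )

    significant = {r.cluster_id for r in results if r.p_adj <= alpha}
    fraction = len(significant) / len(eligible)
    return results, fraction
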