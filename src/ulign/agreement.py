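"""How similarly two alignments use the larger network.

Two statistics, both normalised by the smaller of the two alignments so
they live in [0, 1]:

* node mapping agreement — overlap of the target-side images,
  |S_i ∩ S_j| / min(|S_i|, |S_j|), where S_k is the set of larger-network
  proteins used by alignment k;
* exact mapping agreement — fraction of sources mapped identically,
  |{u : f_i(u) = f_j(u)}| / min(|f_i|, |f_j|).

An identical mapping implies a shared image node, so exact agreement
never exceeds node agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import UndefinedScoreError
from .net_io import Alignment


@dataclass(frozen=True)
class AgreementMatrix:
    labels: tuple[str, ...]
    node_agreement: np.ndarray
    exact_agreement: np.ndarray

    def _offdiag_mean(self, m: np.ndarray) -> float:
        k = len(self.labels)
        mask = ~np.eye(k, dtype=bool)
        return float(m[mask].mean())

    @property
    def mean_node_agreement(self) -> float:
        """Unweighted average over distinct alignment pairs."""
        return self._offdiag_mean(self.node_agreement)

    @property
    def mean_exact_agreement(self) -> float:
        return self._offdiag_mean(self.exact_agreement)


def _co_orient(f_i: Alignment, f_j: Alignment) -> Alignment:
    """Flip f_j if it was produced with source/target roles swapped."""
    if (f_i.source_net, f_i.target_net) == (f_j.target_net, f_j.source_net):
        f_j = f_j.inverted()
    if (f_i.source_net, f_i.target_net) != (f_j.source_net, f_j.target_net):
        raise ValueError(
            f"alignments relate different network pairs: "
            f"({f_i.source_net}, {f_i.target_net}) vs ({f_j.source_net}, {f_j.target_net})"
        )
    return f_j


def node_mapping_agreement(f_i: Alignment, f_j: Alignment) -> float:
    """Overlap of larger-network images, normalised by the smaller image."""
    if len(f_i) == 0 or len(f_j) == 0:
        raise UndefinedScoreError("agreement undefined for an empty alignment")
    f_j = _co_orient(f_i, f_j)
    s_i, s_j = f_i.image(), f_j.image()
    return len(s_i & s_j) / min(len(s_i), len(s_j))


def exact_mapping_agreement(f_i: Alignment, f_j: Alignment) -> float:
    """Fraction of identical protein mappings, w.r.t. the smaller alignment."""
    if len(f_i) == 0 or len(f_j) == 0:
        raise UndefinedScoreError("agreement undefined for an empty alignment")
    f_j = _co_orient(f_i, f_j)
    identical = sum(1 for u, v in f_i.mapping.items() if f_j.mapping.get(u) == v)
    return identical / min(len(f_i), len(f_j))


def agreement_matrix(
    alignments: Sequence[Alignment], labels: Sequence[str] | None = None
) -> AgreementMatrix:
    """Pairwise node- and exact-agreement matrices for >= 2 alignments."""
    if len(alignments) < 2:
        raise ValueError("need at least two alignments")
    if labels is None:
        labels = [a.label for a in alignments]
    if len(labels) != len(alignments):
        raise ValueError("labels and alignments differ in length")
    k = len(alignments)
    node = np.eye(k)
    exact = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            node[i, j] = node[j, i] = node_mapping_agreement(alignments[i], alignments[j])
            exact[i, j] = exact[j, i] = exact_mapping_agreement(alignments[i], alignments[j])
    return AgreementMatrix(tuple(labels), node, exact)
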