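# ulign

Scoring, comparison and unification of global protein–protein interaction
(PPI) network alignments.

## The problem

Globally aligning the PPI networks of two species means finding a
one-to-one correspondence between the proteins of a smaller network
G1 = (V1, E1) and a larger network G2 = (V2, E2) that exposes conserved
wiring and lets annotations be transferred between species.  Because the
underlying subgraph-isomorphism problem is intractable, all practical
aligners are heuristics, they disagree with each other, and there is no
consensus on how their output should be judged.  This package is for
people who *consume* alignments: it does not search for alignments, it
evaluates, compares and combines them.

## What it computes

Given an injective partial mapping f : V1 → V2, let
c = |{(u,v) ∈ E1 : (f(u), f(v)) ∈ E2}| be the number of conserved edges
and i the number of G2 edges induced by the image f(V1).  The nine
quality measures are

| score | definition |
|---|---|
| NC  | \|f\| / \|V1\| — node coverage |
| EC  | c / \|E1\| — edge correctness |
| ICS | c / i — induced conserved sub-structure |
| S³  | c / (\|E1\| + i − c) — symmetric sub-structure |
| LCC | largest connected component of the conserved subgraph, / \|V1\| |
| KP  | mapped pairs sharing a KEGG pathway / min per-network annotated-protein count |
| GO-BP, GO-MF, GO-CC | the same with Gene Ontology terms of one aspect |

On top of the per-alignment scores the package provides:

* **agreement** between two alignments i, j of the same pair — image
  overlap `|S_i ∩ S_j| / min(|S_i|, |S_j|)` on the larger network, and
  the fraction of identical mappings w.r.t. the smaller alignment;
* **benchmarking** — best score over a balancing-parameter sweep,
  competition ranking per measure, rank averages (over all nine measures
  and over S³+KP alone), the geometric-mean S³/KP trade-off, and the
  Pearson correlation matrix of measures across alignments;
* **unification** — the union of several one-to-one alignments into a
  many-to-many mapping with per-pair provenance, cumulative
  coverage-vs-k curves, soft (overlapping) clusters of smaller-network
  proteins keyed by the larger-network protein they map to,
  hypergeometric (sampling without replacement) term enrichment of
  clusters with Benjamini–Hochberg correction, and the consistency of
  annotation transfer from clusters to their target proteins;
* **synthetic fixtures** — seeded generators for network pairs with a
  planted correspondence, noisy alignments and annotation tables, so
  everything is testable without downloads.

## Worked example

```python
from ulign import *

G1 = Network.from_edges("worm", [("a","b"),("b","c"),("c","d"),("d","e")])
G2 = Network.from_edges("fly",  [("v","w"),("w","x"),("x","y"),("y","z"),
                                 ("z","v"),("v","x")])
f = Alignment("worm", "fly", {"a":"v","b":"w","c":"x","d":"y","e":"z"})
print(score_alignment(G1, G2, f))
```

prints

```
{'NC': 1.0, 'EC': 1.0, 'ICS': 0.667, 'S3': 0.667, 'LCC': 1.0}
```

every worm protein is mapped (NC = 1) and all four worm interactions are
conserved (EC = 1), but the image region of the fly network contains six
induced edges of which only four are matched (ICS = S³ = 2/3), and the
conserved subgraph is a single connected path (LCC = 1).  A second
alignment `g` that swaps the partners of `b` and `c` uses exactly the
same fly proteins but maps them differently:

```python
g = Alignment("worm", "fly", {"a":"v","b":"x","c":"w","d":"y","e":"z"})
node_mapping_agreement(f, g)   # 1.0  — same image on the fly network
exact_mapping_agreement(f, g)  # 0.6  — 3 of 5 mappings identical
u  = unify([f, g], labels=["f", "g"])   # 7 (source, target) pairs
sc = soft_clusters(u)  # e.g. fly protein 'w' <- worm cluster {'b','c'}
```

The same operations are available from the shell:

```sh
ulign simulate --out-dir fixtures --seed 7
ulign score --net1 fixtures/net1.tsv --net2 fixtures/net2.tsv \
      --aln fixtures/planted.tsv --out scores.tsv
ulign unify --net1 fixtures/net1.tsv --net2 fixtures/net2.tsv \
      --aln fixtures/planted.tsv --aln fixtures/corrupted.tsv --out unified.tsv
ulign rank --scores sweep.tsv --out ranks.tsv
```

See `docs/methods.md` for the definitions, conventions and numerical
choices in detail.

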