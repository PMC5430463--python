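# Methods

## Scope and model

The package evaluates *given* one-to-one global alignments of undirected
simple PPI networks; it never searches for alignments and never touches
sequences.  A network pair is always oriented canonically — the network
with fewer nodes is the source (ties broken by edge count, then name) —
because every score is anchored to the smaller network.  Alignments
supplied in the opposite orientation are inverted transparently (valid
because one-to-one mappings are invertible).

## Score definitions and conventions

With c conserved edges and i induced target edges (see README for the
formulas): all scores are fractions in [0, 1], higher is better, and
S³ ≤ min(EC, ICS) always holds; whenever EC, ICS > 0 the harmonic
identity S³ = 1/(1/EC + 1/ICS − 1) is an exact consequence of the
definitions and is used as an internal consistency oracle in the tests.

Conventions that the definitions alone do not fix:

* **Missing, not zero.**  A score whose denominator is empty (EC with an
  edgeless source network, ICS with no induced edges, an annotation
  score with no annotated protein) is reported as missing (`None`/`NA`),
  never as 0.  Conflating "nothing to conserve" with "nothing conserved"
  would bias sweep averages and correlations downward.  Note that S³ is
  still defined (and 0) when only one of E1, i is empty; it is missing
  only when both are.
* **LCC counts nodes and is normalised by |V1|.**  Whether the "largest
  aligned connected component" counts nodes or edges is a genuinely open
  convention; node count was chosen, the edge count is exposed alongside
  (`largest_component_counts`), and the normalisation by the smaller
  network's node count makes the value comparable across pairs, which
  averaging and correlation need.  The component is built on the source
  side from the conserved edges; its image in the target is isomorphic,
  so the side is immaterial.  With no conserved edge the value is 0
  (isolated aligned nodes are not counted as components).
* **Annotation scores.**  The denominator is the *smaller per-network
  count of annotated proteins*, where "annotated" means the protein is
  both in the annotation table and a node of that network.  Mapped pairs
  with an unannotated member contribute 0 to the numerator but are not
  removed from the denominator.  Terms match by exact identifier;
  no GO-graph propagation is performed (direct annotations only).
* **Self-loops are dropped on input** (with a logged count) rather than
  rejected: the scores are defined over simple graphs, and homodimer
  edges would otherwise need a conservation convention that does not
  exist.

## Agreement and unification

Both agreement statistics are normalised by the smaller of the two
alignments, which bounds them by 1 and makes them symmetric; exact
agreement ≤ node agreement always (an identical mapping implies a shared
image node).  Matrix averages over alignment panels are unweighted
means over distinct pairs.

The union of alignments is score-agnostic: callers pick which alignment
per aligner enters the union (typically each aligner's best-S³ or
best-KP alignment).  Coverage-vs-k curves take the caller's order (best
aligner first, by convention) and start at 0 for k = 0.  Soft clusters
are keyed by the target protein, so "the cluster's target" is
unambiguous when computing transfer consistency: a cluster counts as
consistent when the union of its members' annotations intersects the
(annotated) target's annotations; unannotated targets are excluded from
the denominator.

## Enrichment

Cluster enrichment uses the hypergeometric upper tail P(X ≥ k)
(sampling without replacement; scipy's survival function, which is
stable for large populations), testing only terms carried by at least
one annotated cluster member — testing absent terms is vacuous and
inflates the correction family.  Clusters need ≥ 2 annotated members to
be eligible; unannotated members carry no information under sampling
from the annotated universe and are ignored for k and n.

Two things the enrichment protocol does not pin down were made explicit
and configurable:

* **Background universe** — default: all annotated proteins (restrict
  with `background=`, e.g. to the source network's nodes, which is what
  the acceptance pipeline does).  Clusters are subsets of source-network
  proteins, so the source-side universe is the natural choice.
* **BH family scope** — default: per cluster, because the question asked
  of each cluster is "does at least one term survive correction?";
  a global family across all (cluster, term) tests is available via
  `bh_scope="global"`.

BH itself is the textbook step-up (sort ascending, p·m/i, enforce
monotonicity from the top, cap at 1), implemented directly and
cross-checked against statsmodels in the tests.

## Benchmarking

For aligners with a topology/sequence balancing parameter α sampled over
{0, 0.1, …, 1}, the per-aligner per-metric summary is the *best over α
of the across-pair mean* (missing values excluded from means; α-ties go
to the smallest α).  Ranking is *competition* ranking — tied aligners
share the minimal rank and the next distinct value's rank is 1 + the
number of strictly better aligners ("1, 1, 1, 4") — which is the only
tie rule consistent with published rank tables of this kind; aligners
are sorted by the mean of their nine ranks, with the mean of the S³ and
KP ranks reported alongside since S³ subsumes the topological and KP
the biological measures.  Score correlations are Pearson over
pairwise-complete rows (min 3 observations per cell); zero-variance
measures yield missing entries rather than arbitrary values.  The
topology/biology trade-off of one alignment is √(S³·KP), which lies
between min and max of its inputs.

## Synthetic generator

The generator exists to make every operation testable without
downloads; it is not a model of PPI evolution, and passing on synthetic
pairs does not certify behaviour on real interactomes (real PPI networks
are noisier, are degree-heterogeneous in ways a perturbed ER base graph
only caricatures, and real aligner outputs are not uniform corruptions
of a planted truth).

Defaults: G1 is Erdős–Rényi G(n1 = 50, p = 0.08) (~100 edges, sparse as
small interactomes are); G2 (n2 = 80) starts as a copy of G1, grows the
extra nodes by preferential attachment (3 edges each, giving hubs) and
has 10% of the copied edges rewired to random non-edges — enough noise
that the planted mapping is imperfect but clearly better than chance.
The annotation generator gives every protein one uniform term from a
20-term vocabulary and adds a shared term to each planted pair with
probability `coherence` (default 0.8), so the planted alignment's
annotation-overlap score is ≈ coherence plus a chance floor, reaching
exactly 1.0 at coherence 1.  `corrupt_alignment` re-targets a chosen
fraction of pairs to *unused* target nodes (never to another pair's
target), so injectivity is preserved and every re-targeted pair is
guaranteed wrong; consequently expected S³ and annotation overlap
decrease monotonically in the fraction, which is the package's stand-in
for "the scores track alignment quality".  All randomness in a generator
call flows from its single integer seed; identical inputs give
byte-identical outputs.

Problem sizes used by the test suite and the acceptance pipeline
(brute-force oracles on ≤ 12-node pairs, Monte-Carlo runs with 50 seeds
on 40–90-node pairs, an end-to-end pipeline at n1 = 60, n2 = 140) were
chosen so that exhaustive enumeration stays exact and Monte-Carlo means
are stable; everything completes in seconds.

## Known limitations

* No GO semantic-similarity scores (they correlate strongly with the
  term-overlap scores and would require ontology data files).
* No consensus one-to-one alignment is derived from the union — the
  many-to-many structure is the point, and collapsing it would need a
  voting rule the evaluation framework does not define.
* The LEDA `.gw` reader covers the plain header/node/edge layout used
  by GRAAL-family tools, not the full LEDA specification.
* File formats are deliberately minimal (edge lists, two-column TSVs);
  database-specific formats (PSI-MI, SIF with interaction types) are out
  of scope.
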