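# Methods

## Graph construction

A subject's functional connectome is a symmetric ROI×ROI Pearson
correlation matrix with unit diagonal (Schaefer-200/17 parcellation; ROI
ids 1–100 left hemisphere, 101–200 right). Construction of the group
graph for a task:

* **Thresholding.** A pair is connected within a subject iff
  r_ij > `r_threshold` (default 0.75), *strictly*: r = 0.75 is excluded,
  and negative correlations are never suprathreshold — the criterion is a
  high positive correlation, not a high magnitude.
* **ROI exclusion.** Networks outside the analysis' scope are removed
  before aggregation; the default exclusion set is the four visual and
  somatomotor networks of the 17-network nomenclature
  ({VisCent, VisPeri, SomMotA, SomMotB}), configurable. Whether adjacent
  networks (e.g. TempPar) should also be excluded is not settled; the
  default keeps them.
* **Aggregation and edge filter.** The group edge weight counts subjects
  with a suprathreshold pair. The reliability filter keeps an edge iff
  its count ≥ `min_subjects` (default 10). We read the filter as
  *edge-level*, with node removal a consequence of isolation: the
  published strength tables bottom out at exactly 10 and contain
  degree-1 nodes of strength 10, which a node-level reading could not
  produce. Isolated nodes are dropped, so the node set lists only
  connected ROIs.

The filter boundaries (0.75 exclusive, 10 inclusive) and their
configurability are part of the module's contract and are covered by
boundary tests.

## Node metrics

Degree and strength are row sums of the binary/weighted adjacency.
Betweenness is unnormalized, endpoints excluded, with even splitting
across tied geodesics. Closeness is 1/Σd over *reachable* nodes only.

Path-based metrics use **binary hop distances by default**. The edge
weights here are participant counts (10–144); treating them as lengths
would be backwards (strong edges are short, not long), and the published
closeness values — exactly 1 for members of isolated dyads — are only
possible under hop distances. An `inverse_weight` scheme (length = 1/w)
is available for weighted sensitivity analyses. Some published closeness
values for large components are not consistent with any single standard
convention we could identify without the original edge lists; closeness
is therefore validated against oracles and hand-derived cases, not
against those numbers.

## Expected force

Implemented from the transmission-cluster definition (entropy of the
force of infection after two susceptible–infected transmission events),
not from the one-line gloss "summing the weights of connections", which
would collapse the score into strength; the two are reported separately
so their divergence is inspectable. For seed i, enumerations J are
ordered pairs (edge₁, edge₂): edge₁ infects a neighbour j of i, edge₂
infects a node outside {i, j} along an edge incident to the infected
cluster — a node reachable through two edges yields two enumerations.
The cluster force d(J) is the total boundary (edge count, or weight sum
in the weighted variant) of the final three-node cluster, and

    ExF(i) = − Σ_J d̄_J ln d̄_J,   d̄_J = π_J d(J) / Σ_K π_K d(K)

with π_J = 1 (unweighted) or π_J = w(edge₁)·w(edge₂) (weighted —
enumerations replicated in proportion to the transmission sequence's
propensity; with equal weights the variants coincide exactly). Natural
logarithm, so values are in nats. If every cluster has zero boundary
(dyads, triangle components) the total force is zero and ExF ≡ 0. The
weighted variant is the default for the pipeline since the group
weights carry the reliability information; whether the original analysis
weighted its influencer score is unknown, so both are exposed.

Hand-derived anchors (star centre ln 6, star leaf ln 2, triangle 0) and
exhaustive enumeration on every connected ≤6-node graph back the
implementation.

## Hubs, influencers, cross-task comparison

Top-fraction selection uses k = ⌈q·n⌉ with a tie-inclusive cutoff, and
the denominator n is the node count of *that task's graph* (55/78/57/54
in the reference tables), not the atlas size — the published initiation
influencer list has exactly ⌈0.2·55⌉ = 11 entries. Hubs are the
intersection of the strength and betweenness top-20% sets; this
intersection rule reproduces the published shared-hub set {72, 182, 189}
from the published per-node tables, which is why it was adopted over a
combined-rank rule. The cross-task table lists every node absent from at
least one task with its per-task degree (NA marks absence).

The packaged reference tables are transcribed verbatim; one internal
inconsistency of the source is preserved rather than corrected (its
distinct-node table lists three shifting nodes, 167/169/175, that the
shifting degree table does not contain), and its initiation
degree-distribution column omits the degree-4 row (printed fractions sum
to 0.945). A checksum test pins the transcriptions.

## Communities and global metrics

Louvain (weighted modularity, seeded and deterministic; default seed 0)
is the primary detector; the divisive edge-betweenness algorithm
recomputes exact edge betweenness (binary distances) after every removal
— O(nm) per step is acceptable at n ≤ 200 — with ties broken by the
lexicographically smallest (source, target) pair, and returns the
maximal-modularity cut of the dendrogram (how the original dendrograms
were cut is unstated; maximal Q is the natural choice). Partitions are
compared by ARI and NMI. Infomap is not implemented: it is never used in
the reported results.

Global conventions, chosen because all four real group graphs are
disconnected (isolated dyads survive the filter): characteristic path
length averages over connected pairs only; global efficiency averages
1/d over all pairs with 0 for unreachable ones; σ =
(C/C_rand)/(L/L_rand) is forced to 0 whenever mean clustering is 0
(exactly the regime of the real graphs, whose transitivity is 0).
L_rand/C_rand come from R = 100 seeded Erdős–Rényi G(n, m) replicates
with matched n and m; the original null model is unstated, so
ratio-based published values (path-length ratio, σ) are treated as
non-reproducible and the machinery is validated by closed forms and
oracles instead. A degree-preserving configuration-model null is
available as an option. Assortativity is the Pearson correlation of
endpoint degrees over both orientations of each edge, undefined (NaN)
for degree-regular graphs.

## Statistics

Kruskal–Wallis (tie-corrected, chi-squared approximation, df = 3) runs
on the strengths of the ROIs present in all four graphs — reproducing
chi-squared = 21.634, p = 7.772e-05 from the reference tables. Pairwise
comparisons use two-sided Wilcoxon rank-sum tests (normal approximation
with tie and continuity correction). The default familywise adjustment
is **Bonferroni**, because it reproduces the published adjusted pairwise
table exactly (e.g. 0.9116 = 6 × 0.15193 for shifting vs 2-back); Holm
and unadjusted modes are provided. The published KS statistics against
random graphs (D = 0.85–0.96) imply a null far from G(n, m) with matched
m and are documented, not targeted; the KS machinery itself is exposed
with ER and configuration nulls. The hub-level KW comparison reported as
p = 0.7965 in the source is ambiguous about its exact inputs and is not
reproduced.

## Synthetic cohorts

The generator emulates the pipeline's input under the study's
conditions: 144 subjects, 200 ROIs with a full 17-network label table,
five planted modules of 12 included ROIs, six planted hub connectors,
per-subject edge probabilities p_within = 0.6 (module edges), p_hub =
0.5 (hub edges), p_background = 0.005 (any other pair), suprathreshold
correlations drawn from U(0.76, 0.95) and the rest from U(0, 0.70).

Design of the planted topology: each module is a circulant lattice
C(1, 3) — cohesive (degree 4) yet triangle-free, so modules survive
Louvain intact while the graph stays in the near-zero-clustering regime
of the real data. Each hub places three edges in a home module and five
across the others, and module nodes accept at most one hub edge each, so
hub strength (≈ 8 × 72) separates structurally from the strongest module
nodes (≈ 4 × 86 + 72) and hubs are the only inter-module bridges (top
betweenness). Under the defaults the group graph is deterministic in
shape (66 nodes, 168 edges, density 0.078): every planted edge's count
is far above the ≥10 filter and background pairs (expected count 0.72)
essentially never reach it.

Correlations are sampled per pair, not from a generative time-series
model, and positive-definiteness is *not* enforced — the pipeline
consumes only elementwise threshold exceedances. Consequently the
synthetic cohorts say nothing about estimation error in the correlations
themselves, about spatial autocorrelation between neighbouring parcels,
or about subject-level covariates; passing recovery tests demonstrate
that the graph-construction, classification and community stages recover
structure that is truly in the matrices, no more.

## Problem sizes and numerics

Oracle suites run exhaustively on the graph atlas (all graphs on ≤7
nodes; expected-force enumeration on connected ≤6-node graphs). The
recovery study uses seeds 0–4 at full cohort size; the calibration study
uses 1,000 null simulations of four groups of 48 (the shared-ROI
comparison's shape). Ties in top-fraction cutoffs expand the selected
set; ties in edge-betweenness removal are broken lexicographically;
Louvain node order is governed by its seed. Degenerate inputs (empty
graphs, empty groups, m = 0 references) raise or return NaN/0 as
documented per function rather than propagating silently.
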