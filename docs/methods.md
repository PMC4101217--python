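# Methods

## The detection problem and the model

Protein complexes appear in protein–protein interaction (PPI) networks as
vertex sets that are densely connected internally and sparsely connected
to the rest of the graph. Two empirical facts shape the design: a protein
can belong to several complexes (complexes overlap), and complexes are
hierarchically organised (large assemblies contain smaller sub-complexes).
The detector here is a seed-expanding local search that accommodates both:
overlap arises because different seeds may grow through the same vertex,
and hierarchy arises by re-running the detector at increasing values of a
single resolution parameter.

### Edge clustering value and the weight transform

For an edge ⟨u, v⟩ with base weights w (1 for unweighted input), with
N(u) the full neighbour set of u and I = N(u) ∩ N(v),

    ECV(u, v) = (Σ_{k∈I} w(u,k) · Σ_{k∈I} w(v,k))
                / (Σ_{s∈N(u)} w(u,s) · Σ_{t∈N(v)} w(v,t)).

On unweighted input this is |I|²/(deg u · deg v) ∈ [0, 1]. N(u) includes
the partner endpoint v; since I never contains u or v in a simple graph
only the denominator is affected, and this convention keeps the
unweighted reduction inside [0, 1]. Each edge is then re-weighted

    w′(u, v) = α + (1 − α) · ECV(u, v) / ECV_avg ,

with ECV_avg the plain arithmetic mean ECV over edges and α the floor
weight for ECV-0 edges. **α defaults to 0.2** (the conventional value for
this transform); α is the residual probability that a locally sparse edge
is still intra-complex, so it should stay well below 1. The mean of w′
over edges is exactly 1 by construction. If every edge has ECV 0 (a
triangle-free graph) the transform is undefined; all weights are set to
1 with a warning, which preserves the mean-1 property and makes every
edge a seed candidate.

### Seeds

Seed edges are the union of (a) edges with w′ not less than the average
weight and (b) *essential PPIs* — edges both of whose endpoints are in
the supplied essential-protein list. Both signals independently enrich
for intra-complex edges; their union covers complexes that carry only one
of the two signals. The queue is ordered by nonincreasing weight, then
essential-first, then lexicographically by the canonical (sorted) edge so
runs are platform-independent. Ablation strategies (`ecv_only`,
`essential_only`, `random` with a required RNG seed; `random` matches the
union set's cardinality) exist to quantify what the seed choice buys.

### Expansion and the λ-module stopping rule

A growing cluster H absorbs, one vertex at a time, the outside vertex v
maximising the cluster property f(v, H) = Σ of w′ over edges from v into
H (candidates are restricted to f > 0, so H stays connected; ties go to
the lexicographically smallest ID and are logged). Growth stops when H
is a λ-module:

    λ(H) = Σ_{v∈H} d_in(v, H) / Σ_{v∈H} d_out(v, H) ≥ λ_th ,

weighted in-degree over weighted out-degree (each internal edge counted
from both ends; λ = +∞ when no edge leaves H). The λ test runs **before**
each growth step, starting at the 2-vertex seed, so two-protein complexes
are expressible. If a component is exhausted before the test passes, the
cluster is emitted with λ = +∞.

Overlap control: checked before the λ test, on the seed pair and after
every addition — if strictly more than half of H's vertices already
belong to previously output complexes, the expansion is abandoned.
Abandoned clusters mark no vertices and do not prune the queue; the
popped seed is consumed either way. After each *output* complex its
members are marked and every queue entry with ≥ 1 marked endpoint is
removed. The one-endpoint reading of the pruning rule (rather than
both-endpoints) is a genuine open choice; it is the stricter reading and
produces fewer, less redundant complexes.

### Hierarchy

Layers are independent full runs at a strictly increasing λ ladder,
default **0.25, 0.5, 1, 2, 4, 8, 16**. A child complex at one threshold
links to a parent at the next threshold when |child ∩ parent| / |child| ≥
0.5 (all qualifying parents are linked); when no parent qualifies, the
best-overlapping parent is still recorded, flagged. The containment
coefficient and the 0.5 default are this package's own quantitative
choices — inclusion between layers is usually shown pictorially, not
defined — and the threshold is exposed (`link_threshold`).

### Evaluation

Predicted and reference complexes match when the overlap score
OS(A, B) = |A∩B|²/(|A|·|B|) reaches a threshold (default 0.2, the
conventional value). Specificity = fraction of predicted complexes
matched (a predicted complex matching several references counts once);
sensitivity = fraction of reference complexes matched; F-score = their
harmonic mean. Sensitivity inflates with the number of predictions, so
reports flag it as size-sensitive. Set summaries use the standard induced
edge density 2m/(n(n−1)) on the unweighted graph and the overlapping rate
Σ|Cᵢ|/|∪Cᵢ| (= 1 iff pairwise disjoint).

## Numerical choices

* **Seed threshold comparison.** "Weight not less than the average" is
  compared against the mean minus 1e-9 (absolute; weights are O(1)). In
  exact arithmetic the mean is 1, but the summed floating mean drifts by
  a few ulps, and an exact comparison would arbitrarily drop edges whose
  weight is exactly 1 — observable already on a 6-edge toy graph. The
  slack is far below any meaningful weight difference.
* λ and f are maintained incrementally during expansion; the test suite
  holds them to brute-force recomputation at ~1e-15.
* Degenerate inputs: empty edge set → error; all-zero ECV → constant
  weight 1 + warning; singleton clusters are rejected by λ/density
  contracts; complexes of size < 2 are never emitted (seeds are edges).
* Determinism: the only randomness is the `random` seeding strategy and
  the generator, both behind an explicit `rng_seed` (numpy Generator);
  identical inputs and seeds give byte-identical output files (no
  timestamps in provenance headers).

## The synthetic generator

`generate_planted` plants `n_complexes` vertex sets (sizes uniform in
`size_range`) in a background of `n_background` extra vertices.
Intra-complex pairs are edges with probability `p_in` plus a spanning
path (truth complexes are guaranteed connected); all other pairs with
probability `p_out`; with probability `overlap_frac` a complex shares one
vertex with its predecessor, which exercises the abandonment rule.
`essential_frac` of each complex's members plus 5% of background vertices
are labelled essential, mirroring the enrichment of essentiality inside
complexes that motivates essential seeds.

Defaults — 10 complexes, sizes 5–8, p_in = 0.9, p_out = 0.02, overlap
0.3, essential fraction 0.5, 50 background vertices — give a sparse
network (~115 vertices) whose planted subgraphs are unambiguous at these
densities; they are the fixed study conditions of the recovery and
ablation checks, not tuning knobs. What the generator does **not**
emulate: scale-free degree structure, false-positive/negative interaction
noise patterns of specific assays, and the size distribution of curated
catalogues. Passing recovery tests therefore demonstrate algorithmic
correctness under controlled planted structure, not expected accuracy on
a real interactome.

Problem sizes used by the test suite and the acceptance script — 20
generator seeds for recovery/ablation means, 20 fixtures × 7-layer ladder
for the trend fractions, 200 random graphs of ≤ 12 vertices for oracle
agreement — are chosen so each planted network is small enough to verify
by brute force while large enough that the statistical properties are
stable across seeds.

## Known limitations

* The queue-pruning semantics (one marked endpoint removes an edge) and
  the f tie-break are under-determined by the λ-module framework itself;
  both choices change exact complex counts on real data, which is why
  reproduction of published counts on curated networks is expected only
  to within a few percent.
* Expansion has no size cap; on a graph that is one dense blob with a
  huge λ_th, a single complex can swallow a whole component (by design —
  the +∞ convention).
* Layers are computed independently; the hierarchy links are a post-hoc
  association, not a constraint, so a child may have no qualifying
  parent (it is then linked to its best overlap, flagged).
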