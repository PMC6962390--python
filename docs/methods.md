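# Methods

## Model

A network is an undirected, unweighted simple graph G(V, E): no self-loops,
no parallel edges, opaque node labels (strings when read from file; no
numeric coercion, since real edge lists mix integers and names). U is the
set of all N(N−1)/2 unordered node pairs and L = U − E the candidate
(missing-link) set. A similarity index assigns every candidate pair a
nonnegative, symmetric, finite score S_xy; higher means "more likely to be
a missing/future edge".

The central index is CCPA,

    S_xy = α·|Γ(x) ∩ Γ(y)| + (1 − α)·N/d_xy ,   α ∈ [0, 1],

a zero-sum blend of the common-neighbor count and a pairwise closeness term
N/d_xy (node count over shortest-path hop distance). N is the node count of
the network being scored — during evaluation, the training network, whose
node set equals the source graph's. The eight baselines (CN, CND, PA,
Adamic–Adar, resource allocation, Jaccard, Sørensen, hub-promoted) follow
their textbook definitions; see `ccpalink.similarity`.

Numerical conventions, applied uniformly and exercised by tests:

- Distances are BFS hop counts (graphs are unweighted, so BFS is exact);
  a disconnected pair gets the sentinel `inf`, never a large finite number.
  The distance terms N/d (CCPA) and 1/d (CND) are 0 for disconnected pairs
  — the d → ∞ limit — rather than an error.
- Zero denominators (isolated endpoints, empty neighborhood unions) score
  0: such pairs are maximally dissimilar, and the evaluation protocol must
  still be able to score them.
- Adamic–Adar's logarithm is the natural log. Every common neighbor of a
  simple-graph pair has degree ≥ 2, so terms are finite.
- Ranking ties break lexicographically on the canonical (sorted) pair
  labels, making ranked output byte-stable.

## Evaluation protocol

Observed edges are split uniformly at random without replacement into
E^T (training, |E^T| = round-half-up(fraction·M), capped at M−1 so at least
one probe edge remains) and E^P (probe). The training graph keeps the full
node set; isolated training nodes are legal and score via the zero
conventions — there is deliberately no connectivity repair. All degrees,
neighborhoods and distances are computed on the training network only,
never the full graph, which would leak the held-out edges.

AUC = (n1 + 0.5·n2)/n compares probe edges against non-existent links.
Negatives default to U − E (absent from the *full* observed graph), so
probe edges are never counted as negatives; `negative_pool="training"`
switches to U − E^T for comparison with protocols that allow it. Two
floating-point scores within 1e-12 count as a tie (n2). Comparison count:
exhaustive over every (probe, negative) pairing when that product is at
most 10^6, otherwise 10^5 independently sampled uniform pairings — both
choices keep a karate-club-sized run well under a second while the sampled
mode stays within binomial error of the exhaustive value (tested at three
standard errors).

Defaults mirror the standard protocol: training fraction 0.8, 15 repeated
splits, α grid {0.1, …, 0.9}. Mean and *sample* standard deviation
(n−1 denominator) summarize the per-run AUCs. Per-run seeds come from a
SplitMix64-style mix of (base_seed, run index), so extending a run count
never perturbs earlier runs, and identical inputs reproduce reports
byte-for-byte. The α sweep reuses the same base seed for every α, making α
the only varying factor.

### A structural note on the α sweep

Candidate pairs are non-adjacent, and for non-adjacent pairs a shared
neighbor forces d = 2; hence CN ≥ 1 ⇔ d = 2. For any α ∈ (0, 1) every
common-neighbor pair therefore outranks every zero-CN pair
(α·CN + (1−α)·N/2 > (1−α)·N/d for d ≥ 3), within the CN group the order is
by CN alone, and within the zero-CN group by 1/d alone: the ranking — and
with it the AUC on a fixed split — is *independent of α on the open
interval*. Only the endpoints change tie structure (α = 1 collapses all
zero-CN pairs to score 0; α = 0 collapses equal-distance pairs). With
splits held fixed across the grid, the sweep consequently reports identical
AUCs for α = 0.1 … 0.9; per-α variation reported in studies that resample
splits per α is split noise, not an α effect. Two further exact
coincidences follow from rank invariance: Jaccard = S/(2−S) is a monotone
transform of Sørensen (identical AUCs always), and CND induces the same
ranking as CCPA with α ∈ (0, 1) (same partition, same within-group orders),
so their AUCs coincide on any fixed split.

## Synthetic data

The generators exist so everything is testable without downloads:

- `fixture_g5` — a fixed 5-node graph (triangle + 2-edge tail) small enough
  that every index value in the test suite is hand-evaluated.
- Seeded Erdős–Rényi, Barabási–Albert and Watts–Strogatz models (networkx
  generators, relabelled to string nodes so edge-list round trips are
  exact; identical spec ⇒ byte-identical output).
- `planted_benchmark(n, planted_fraction, seed)` — consecutive communities
  of 12 nodes, within-community edge probability 0.6, background 0.02, with
  a seeded 20% (default) of realized intra-community edges removed and
  returned as the "future" set. Defaults were chosen once to emulate the
  triadic-closure regime of social/biological networks at desk scale:
  communities dense enough that a removed edge's endpoints retain several
  common neighbors, background sparse enough that uniform non-edges are
  predominantly inter-community. What passing on this benchmark shows is
  that the harness correctly rewards a scorer matched to the planted
  mechanism; it does not show that any index is best on real networks,
  whose degree heterogeneity, clustering spectra and noise it does not
  emulate. Real benchmark datasets are not bundled; any edge-list file can
  be supplied to the CLI instead (for karate, `networkx.karate_club_graph`
  is used directly).

## Summary statistics

`network_summary` reports N, M, <k> = 2M/N (exact), and <d> as the mean
BFS distance over *connected unordered pairs* — disconnected pairs are
excluded from numerator and denominator, so the statistic stays defined on
fragmented graphs (and is NaN, reported as JSON null, when no pair is
connected). Published tables do not always state their <d> convention; this
one is documented as the package's own.

## Problem sizes

Test and acceptance workloads are sized for interactive use: oracle and
invariant sweeps use batteries of 100 seeded 14–16-node random graphs;
AUC calibration uses 60–96-node planted benchmarks; the acceptance script's
protocol runs use the 34-node karate network with exhaustive comparisons.
The whole suite runs in seconds.

## Known limitations

- Directed, weighted, bipartite and temporal graphs are out of scope, as
  are embedding/learning-based scores and a betweenness variant of the
  centrality term.
- Whether published protocols drew negatives from U − E or U − E^T is often
  ambiguous; U − E is the default here and the alternative is exposed, not
  asserted as anyone's choice.
- `avg_distance` on large graphs costs one BFS per node (O(N·M)); the
  summary is not intended for million-edge graphs.
- Scores of 0 from the degenerate-denominator conventions are
  indistinguishable from "genuinely dissimilar" in downstream ranking; the
  AUC's tie handling absorbs this, but threshold-based consumers should be
  aware.
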