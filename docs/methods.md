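# Methods

## Model and objective

`modclust` treats the input as a simple undirected graph over opaque
string node identifiers. Self-loops and duplicate edges are dropped at
construction (with a logged count) because the modularity machinery
assumes a simple graph; node IDs are case-sensitive and only surrounding
whitespace is trimmed, since identifier schemes such as Ensembl IDs are
case-stable and more aggressive normalisation risks collisions.

All clustering is driven by Newman–Girvan modularity. For a disjoint
partition of a graph with `m` edges,

    Q = Σ_c [ e_c/m − (d_c/(2m))² ]

with `e_c` the internal edge count and `d_c` the summed degree of
cluster `c`. The weighted generalisation used on coarsened graphs
replaces counts by weights and degrees by strengths; a self-loop
contributes its weight once to the internal weight and twice to the
strength, so that total strength equals `2W` and the singleton partition
of a quotient graph has exactly the modularity of the partition it
encodes. The merge gain used by the agglomerative phase is the closed
form `ΔQ(a,b) = l_ab/m − d_a d_b/(2m²)`; the transfer gain for moving
vertex `v` from `a` to `b` is
`(l_vb − l_va)/m − k_v(d_b − d_a + k_v)/(2m²)`. Both are maintained
incrementally and are checked in the tests against a from-scratch
recomputation to 1e−9.

### Overlap modularity

For overlapping covers (OCG) we use the node-splitting form

    Q_ov = (1/2m) Σ_c Σ_{i,j ∈ c} [A_ij − k_i k_j/(2m)] / (f_i f_j)

where the inner sum runs over ordered pairs including `i = j` and `f_v`
is the number of clusters containing `v`. The ordered-pair convention is
deliberate: it makes `Q_ov` collapse *exactly* to `Q` whenever every
`f_v = 1`, which the tests exercise as the disjoint-limit safety net for
the overlap machinery. (The i<j convention, sometimes seen, does not
have this property — it drops the diagonal `−k_i²/2m` terms.)

## Search procedures

**FT (fusion-transfer).** Start from singletons; repeatedly apply the
cluster merge with the largest positive `ΔQ` (ties broken by the
lexicographically smallest cluster-ID pair); then run vertex-transfer
sweeps — each vertex to its best adjacent cluster while the gain exceeds
`tol` — until a sweep makes no move. A vertex may leave to form a new
singleton only when `allow_split` is set (off by default). Because pure
greedy agglomeration can stall in local optima whose escape would
require a temporarily negative move (we keep a 6-node witness in the
test suite's random ensemble), `ft_partition` restarts the search
`n_restarts` times (default 8): the first run is the canonical
best-improvement procedure, subsequent runs pick merges
first-improvement over a seeded-shuffled candidate list, and the run
with the highest final Q wins. The result is still deterministic given
the seed, and the accepted-move modularity trace of the winning run is
strictly increasing beyond `tol`.

**TFiT (iterated transfer-fusion).** Louvain-style multi-level search:
within a level, vertices start as singletons and are repeatedly
transferred to the best adjacent cluster while the (weighted) modularity
gain exceeds `tol`, in a seeded order; when a level converges, the
partition is collapsed into a weighted quotient graph whose loop weights
carry the internal edge weight, and the procedure recurses until a level
makes no move. Assignments are composed back down to the original
nodes. The level procedure is order-dependent, so the same
`n_restarts`-best-of scheme is applied with seeds derived from the main
seed.

**OCG (overlapping cluster generator).** The initial class system is one
of: every edge; the maximal cliques (Bron–Kerbosch, via networkx); or
*centered cliques* (default) — for each vertex in ID order, greedily
grow a clique among its neighbours in descending-degree order.
Duplicate classes and classes contained in another class are dropped.
Fusion then repeatedly merges the class pair with the largest positive
`ΔQ_ov`, candidates being pairs that share a node or are joined by an
edge; ties prefer the smaller combined size, then member order. Fusion
stops when no merge gains more than `tol`. Classes contained in another
class are removed once more at the end — not after every merge, so that
the accepted-move `Q_ov` trace stays monotone — and the survivors are
renumbered. The gain of a merge accounts for the membership-count
change of shared nodes in *all* classes containing them. The
implementation recomputes class contributions directly (no incremental
`l_ab` structure), which is quadratic in the number of classes; OCG is
intended for networks up to a few thousand edges, while TFiT is the
choice for interactome-scale graphs.

Cluster IDs in every output are canonical: consecutive integers from 1,
ordered by decreasing cluster size, ties by lexicographically smallest
member. Disconnected inputs are allowed; components can never merge
since `l_ab = 0` makes every cross-component gain negative.

## Enrichment statistics

The hypergeometric upper tail `P(X ≥ k)` is computed exactly with
integer binomials and a single rational division — not via a `1 − CDF`
route — so the tiny p-values a strong enrichment produces carry no
cancellation error; the tests compare it against full enumeration of all
`C(N, n)` draws for every `N ≤ 12` and against `scipy.stats.hypergeom`
on larger random cases.

By default the background universe is the *annotated* nodes of the whole
graph: `N` = annotated nodes, `K` = annotated nodes carrying the term,
`n` = annotated nodes in the cluster. This matches the convention of
reporting percentages "among the annotated nodes" and avoids inflating
enrichment with nodes that could never carry any term; counting every
node instead is available with `background="all-nodes"`. Only terms with
`k ≥ 1` in a cluster are tested, clusters below `min_cluster_size`
(default 5) are skipped, and Benjamini–Hochberg runs once across all
(cluster, term) records of a run (`bh_scope="per-cluster"` restricts the
family to each cluster). A record is *enriched* when `p_adj < α`
(strict, default α = 0.05) and passes the *majority rule* when
`100·k/n ≥` the threshold (inclusive, default 50%). For overlapping
partitions a shared node contributes to the counts of every cluster
containing it, while `K` and `N` are computed once on the graph.

Manual cluster tags are bookkeeping only: they appear in the cluster
list's annotation column flagged `(manual)` and never enter the
statistics. Exported tables render p-values in scientific notation with
three significant digits; all comparisons use the raw floats.

## Quotient graph conventions

An edge contributes to the inter-cluster weight of `(A, B)` iff it joins
a node whose membership includes `A` but not `B` to a node whose
membership includes `B` but not `A`; an edge between two nodes shared by
both clusters counts as internal to both and to no inter edge, so the
same adjacency is never counted as both "shared nodes" and "links". The
overlap weight is exactly `|A ∩ B|`. For disjoint partitions the
invariant `Σ internal + Σ inter = m` holds and is asserted in tests and
logged by the CLI. Metanode size is the node count; rendering
proportionality is left to the viewer.

## Synthetic data

`make_sbm` samples a stochastic block model: each within-block node pair
is an edge with probability `p_in`, each between-block pair with
`p_out`, independently, from a seeded generator; isolated nodes are
retained. It emulates the community structure of an interactome at
benchmark scale but none of its degree heterogeneity (no hubs, no
degree-corrected variant), so passing recovery tests demonstrate
correctness of the optimisation machinery, not performance on heavy-
tailed real networks.

`make_annotations` annotates each (node, term) pair independently at
`background_rate`, multiplied for planted (cluster, term) pairs (capped
at 1 with a warning), then thins to an exact `coverage` fraction of
nodes; a catch-all term tops up covered nodes that drew nothing, which
keeps the enrichment background controllable. Real annotation corpora
are hierarchical and strongly correlated between terms; this generator
is deliberately independent per term, which is the right null for
calibration tests but optimistic for sensitivity on correlated term
sets.

Benchmark conditions used by the tests and the acceptance script, chosen
once from a priori power considerations: recovery uses 4 blocks × 20
nodes with `p_in = 0.3`, `p_out = 0.02` (expected within-degree ≈ 5.7
versus between ≈ 1.2, comfortably above the detectability threshold at
this size) on the fixed seed-7 graph across 100 algorithm seeds;
enrichment sensitivity uses 4 blocks × 50 with 20 terms at background
rate 0.2 and one term per cluster planted at 3× (expected `k ≈ 30/50`
against a null mean of 15, per-test power ≥ 0.95 at the BH-adjusted
threshold); null calibration uses the same 80-node graph with purely
random annotations at coverage 0.9 over 50 replicates.

## Numerical choices and degenerate inputs

* `tol = 1e-12` on every accepted move; seeds default to 42 in the CLI
  and are mandatory in the library generators.
* Modularity is undefined on edgeless graphs — all clustering entry
  points raise; empty networks and empty clusters are rejected.
* Density of a singleton (or empty) cluster is 0 by convention.
* Ties everywhere resolve by deterministic keys (IDs, sizes, member
  order), making every output bit-for-bit reproducible given the seed.
* `n_restarts` defaults to 8 for FT and TFiT; restart seeds are derived
  from the main seed and stay below 2³¹.

## Known limitations

* FT's agglomerative phase rescans candidate merges per step (no heap),
  making it quadratic-ish; use TFiT for graphs beyond ~10⁴ edges.
* OCG's fusion is quadratic in the number of initial classes; the
  `edges` initial system on dense graphs is the slowest combination.
* No modularity resolution-limit correction: very small modules attached
  to large ones can be absorbed.
* Annotation terms are tested exactly as given — no ontology-aware
  propagation to ancestor terms, no term de-redundancy.
* Heuristic, order-dependent search: cluster *numbers* are canonical,
  but cluster *content* on degenerate instances can change with the seed
  even though the modularity value is stable.
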