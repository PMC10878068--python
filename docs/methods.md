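# Methods

## Filtering model

A hypergraph is an ordered node set plus an ordered list of hyperedges, each
a non-empty set of node labels. Multi-edges are representable; preprocessing
removes them. The size filtering with operator `*` and parameter `k ≥ 1`
keeps the edges whose size satisfies `|e| * k` and retains the **full node
set** of the parent. This node convention (rather than restricting to the
giant component or to the nodes induced by surviving edges) is what makes
nodal measures directly comparable across filterings; its price is that
filterings routinely contain isolated nodes, and every measure below states
how it treats them. Filtering sets (one filtering per `k` in a list) support
disjointness testing and multiset union; the union uses per-edge multiplicity
`max` across members so that the full uniform set reconstructs the base
hypergraph exactly even in the presence of multi-edges, without double
counting edges shared by overlapping members.

Preprocessing mirrors standard hyperedge-list hygiene and runs in a fixed
order: deduplicate edges by set equality of membership (keeping the first
occurrence), drop singleton edges, then drop nodes left with degree zero.
The operation is idempotent; an input reduced to zero edges is an error
rather than an empty result.

## Global measures

**Effective information.** Computed on the *weighted* clique projection
`w(i, j) = #\{e : i, j ∈ e\}` over non-isolated nodes. Row `i` normalized to
unit ℓ1 norm is the out-transition distribution `W_i^out` of a random walk;
`EI = H(⟨W_i^out⟩) − ⟨H(W_i^out)⟩` with entropies in base 2, so EI is in
bits and satisfies `0 ≤ EI ≤ log2(n_active)`. The normalized variant
divides by `log2(n_active)` — the maximum achievable entropy of the mean
distribution — giving a `[0, 1]` range; the normalization flag is recorded
on the result. Projection weights count co-memberships rather than being
binarized, preserving multiplicity in the transition probabilities (a
`binarize` flag exists for the alternative convention). A filtering with no
edge of size ≥ 2 has no projection and EI is reported as NaN ("not
defined"), not zero: a uniform filtering at a size absent from the data is
a different statement than a filtering with zero information.

**Dynamical assortativity.** `ρ = ⟨k⟩²⟨k k₁⟩_E / ⟨k²⟩² − 1`, with degree
moments over non-isolated nodes and `⟨k k₁⟩_E` the expected product of
degrees over distinct node pairs within hyperedges. The prose definition of
that expectation admits two weightings; the default takes the mean over
pairs within each edge and then over edges, so each hyperedge contributes
equally regardless of size, and a `pair_weighting="pooled"` switch averages
over all (edge, pair) observations instead. Both are oracle-tested. `ρ` is
exactly 0 for degree-regular hypergraphs. Note a finite-size effect worth
knowing: on uniform random hypergraphs `ρ` has a small negative bias of
order `1/n` (co-membership in an edge raises both endpoint degrees jointly);
measured means over seeded draws shrink from −0.017 at n = 20 to −0.0013 at
n = 80, and the test suite asserts exactly this vanishing-bias property
rather than a spurious "mean is zero at any size".

**Pearson variants.** Per hyperedge, degree pairs are selected by rule —
top-bottom `(max, min)`, top-2 (two largest; ties are resolved by sorting
degree values, which cannot change the selected pair), or uniform (all
unordered distinct pairs, one observation each, enumerated exhaustively
rather than sampled). The pooled observations are symmetrized (each pair in
both orders) before the Pearson correlation, making the result invariant to
within-pair order. Full degrees are used by default; a
`degree_mode="excess"` switch subtracts 1 everywhere, which provably leaves
the correlation unchanged (a constant shift of both coordinates) and exists
for parity with excess-degree formulations. Zero variance in either
coordinate — e.g. any degree-regular filtering — yields NaN with a log line.

## Nodal measures

**Betweenness.** Shortest paths are walks in which consecutive nodes share
at least one hyperedge, i.e. unweighted shortest paths on the *binarized*
clique projection; the weighted projection is deliberately not used for
distances. Values come from Brandes' algorithm (networkx) and sum
`σ_uv(n)/σ_uv` over unordered pairs; pairs in different components
contribute nothing, so disconnected filterings need no repair, and isolated
nodes score 0. Optional normalization divides by `(N−1)(N−2)/2` with `N`
the node's *component* size (not the global node count), so scores remain
comparable across components of a fragmented filtering.

**Spectral communities.** The normalized hypergraph Laplacian
`L = I − D_v^{−1/2} B D_e^{−1} Bᵀ D_v^{−1/2}` is built on the incidence
structure of the non-isolated nodes with unit edge weights (no edge-weight
generalization is used). Its spectrum lies in `[0, 2]` and the multiplicity
of eigenvalue 0 equals the number of connected components — both are
asserted against dense eigendecompositions in the tests. The bottom `c`
eigenvectors are clustered with k-means. Determinism per `(H, c, seed)` is
engineered explicitly: eigenvectors get a fixed sign convention
(largest-magnitude entry positive), the eigenproblem is solved densely below
500 active nodes (shift-inverted Lanczos with tolerance 1e−9 above), and
k-means runs 20 seeded restarts keeping the best inertia. Isolated nodes
receive the sentinel label −1 — the least-assumption choice among the
standard ways of labeling nodes outside the covered structure; downstream
agreement scores simply exclude them.

**Label alignment.** Two labelings over the same node set are aligned by
building the confusion matrix over nodes assigned in both, solving the
assignment problem (Hungarian algorithm) maximizing total overlap, and
relabeling the second labeling by the optimal permutation; its unmatched
labels receive fresh indices. Agreement = matched overlap / co-labeled
nodes; NaN when no node is assigned in both. In sweeps every filtering's
labeling is aligned to the full hypergraph's reference labeling, so a label
index means the same community at every `k` and filter type.

## Synthetic data

The generators produce the study conditions for all tests and experiments;
they draw distinct hyperedges by rejection sampling so requested edge-size
spectra are met exactly, and are deterministic given their seed.

* `random_uniform_hypergraph(n, m, k, seed)` — m distinct size-k edges
  uniform over all `C(n, k)` subsets; the structureless null.
* `planted_partition_hypergraph` — each edge is, with probability `p_in`,
  drawn from one community (chosen proportional to community size, keeping
  per-node exposure roughly uniform), else from all nodes.
* `size_stratified_hypergraph` — the headline construction: defaults plant
  two *crosscutting* bipartitions of 64 nodes (contiguous halves vs.
  recombined quarters, 50% overlap) with 80 dyads + 60 triads on partition A
  and 40 five-edges + 30 six-edges on partition B at `p_in = 1`. The sizes
  are chosen so each stratum alone is well connected (mean stratum degree ≈
  5) and small enough that the whole experiment over 20 seeds runs in
  seconds; full bias makes the per-stratum recovery exact, which is the
  regime the recovery claim is about. Size 4 is deliberately absent so the
  sweep exercises its explicit-NaN path.

What the generators emulate is heterogeneous edge sizes with size-dependent
community structure. What they do not emulate: heavy-tailed degree
distributions (no Chung–Lu-style variant in v1), overlapping or nested
communities, temporal structure, or noise edges within strata at the
default bias. Passing the recovery tests therefore shows the pipeline
separates scale-stratified structure when it is present and clean; it does
not bound performance on noisy empirical data, where filtered views are
sparser and more fragile.

## Numerical and design choices

* Entropy base 2 throughout; EI tolerances in tests are 1e−12 against the
  closed form `EI(K_n) = log2 n − log2(n−1)`.
* Oracle comparisons (assortativity, betweenness, Hungarian agreement) are
  asserted to 1e−10 on exhaustive small random instances.
* Degenerate inputs: empty filterings give all-zero centrality, sentinel
  labels and NaN global metrics; metric tables keep those rows and
  serialize NaN as the token `NA`.
* Sweeps default to `k` from 2 to the maximum observed edge size, since
  preprocessing removes singletons.
* The CLI is a thin logged wrapper over the library; results go to files or
  stdout, logs to stderr, and repeated runs with the same inputs and seed
  are byte-identical.

## Limitations

Spectral clustering with a user-fixed global `c` across a sweep keeps labels
comparable but can be the wrong `c` for an individual filtering; no model
selection is attempted. Betweenness on the clique projection discards edge
multiplicity in distances by construction. The dense eigensolver bounds the
comfortable problem size to a few thousand active nodes; beyond that the
Lanczos path engages but k-means cost grows linearly in nodes per restart.
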