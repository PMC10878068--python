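# hyperfilter

Size-dependent filtering and structural profiling of higher-order networks
(hypergraphs).

Many empirical systems — group emails, co-authorship, protein complexes —
contain interactions among more than two entities at once. Analyses usually
assume every interaction, whatever its size, contributes to one consistent
picture of the dataset's structure. Often it does not: connection patterns
are *stratified by interaction size*, and aggregating them hides structure
that exists only at particular scales. `hyperfilter` makes that stratification
visible by decomposing a hypergraph into size filterings and profiling each
one with global and nodal structural measures. It is aimed at network-science
and systems-biology practitioners working with hyperedge-list datasets.

## The model

A hypergraph is `H = (V, E)` with hyperedges `e ⊆ V`, `|e| ≥ 1`. For a
filtering parameter `k` and comparison operator `*`, the size filtering
`H_(*,k)` keeps the edges `{e ∈ E : |e| * k}` and **all** nodes (so nodal
measures remain comparable across filterings). Four operators are provided:

| filtering | operator | use |
|---|---|---|
| uniform   | `=` | isolate one interaction size |
| GEQ       | `≥` | drop low-order interactions |
| LEQ       | `≤` | drop higher-order interactions |
| exclusion | `≠` | remove one anomalous size |

Each filtering is profiled with:

* **Effective information** on the weighted clique projection,
  `EI = H(⟨W_i^out⟩) − ⟨H(W_i^out)⟩` (Shannon entropies in bits, `W_i^out`
  the ℓ1-normalized co-membership row of node `i`): the strength of unique
  associations.
* **Dynamical degree assortativity**
  `ρ = ⟨k⟩²⟨k k₁⟩_E / ⟨k²⟩² − 1`, plus three Pearson variants (top-bottom,
  top-2, uniform pair selection within each hyperedge).
* **Betweenness centrality** `BC(n) = Σ_{u≠v≠n} σ_uv(n)/σ_uv` on shortest
  co-membership paths (Brandes on the binarized clique projection).
* **Spectral communities** from the normalized hypergraph Laplacian
  `L = I − D_v^{−1/2} B D_e^{−1} Bᵀ D_v^{−1/2}` with k-means on the bottom
  `c` eigenvectors; labelings are aligned across filterings by Hungarian
  matching on the confusion matrix.

A seeded synthetic-data module generates uniform random, planted-partition
and *size-stratified* hypergraphs (different community structure on small
and large edges) so every claim is testable end to end.

## Worked example

`examples/04_stratified_recovery.py` plants one bipartition on edges of
sizes 2–3 and a different, crosscutting bipartition on edges of sizes 5–6
over the same 64 nodes, then clusters three views of the data:

```
hypergraph: 64 nodes, sizes {2: 80, 3: 60, 5: 40, 6: 30}
ARI(leq3 clustering, partition A): 1.0
ARI(geq4 clustering, partition B): 1.0
ARI(full clustering, partition A): -0.016
ARI(full clustering, partition B): 1.0
```

The LEQ filtering recovers the small-edge partition exactly and the GEQ
filtering the large-edge one (adjusted Rand index 1.0), while clustering the
whole hypergraph matches only one of the two — the aggregate view loses a
scale. The other scripts in `examples/` walk through the filtering algebra,
the global measures, nodal measures, and the full sweep table.

## Command line

```sh
hyperfilter preprocess --input raw.json --output clean.json
hyperfilter filter geq5 --input clean.json --output big.json
hyperfilter sweep --input clean.json --output table.csv \
    --filters eq,geq,leq,neq --metrics ei_norm,rho_dyn,community --seed 0
hyperfilter generate --config spec.cfg --output synthetic.json --seed 3
```

`sweep` emits a tidy CSV (`filter_type, k, metric, scope, value, seed, c`);
metrics undefined for a filtering (e.g. the uniform filtering at a size with
no edges) are written as the literal token `NA`, never dropped. Hypergraphs
are read from delimiter-separated hyperedge lists or the public hypergraph
JSON dialect (`{"nodes": [...], "edges": [[...], ...]}`).

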