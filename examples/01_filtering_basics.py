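"""Build a small hypergraph and decompose it with the four size filters.

A hypergraph's edges can mix very different interaction sizes; the four
filterings — uniform (= k), GEQ (>= k), LEQ (<= k), exclusion (!= k) —
select them by size while keeping the full node set, so per-node results
stay comparable across filterings.
"""

from hyperfilter import Hypergraph, filtering_set, is_disjoint, size_filter, union_filterings

H = Hypergraph(edges=[{1, 2}, {2, 3}, {1, 2, 3}, {2, 3, 4, 5}, {1, 3, 4, 5, 6}])
print(f"base hypergraph: {H.num_nodes} nodes, {H.num_edges} edges")
print("edge sizes:", H.edge_size_distribution())

for designation in ("eq3", "geq3", "leq3", "neq3"):
    Hf = size_filter(H, designation)
    print(f"{designation}: kept {Hf.num_edges} edges of sizes {Hf.edge_sizes()}, "
          f"nodes retained: {Hf.num_nodes}")

# the full uniform filtering set partitions the edge set and reassembles H
sizes = sorted(set(H.edge_sizes()))
FS = filtering_set(H, "eq", sizes)
print("uniform set disjoint:", is_disjoint(FS))
print("union reconstructs base:", union_filterings(FS) == H)
# Expected: every filtering keeps all 6 nodes; the uniform set is disjoint
# and its union gives back the original hypergraph exactly.
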