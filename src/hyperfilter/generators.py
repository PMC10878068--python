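"""Synthetic hypergraphs with controlled, size-stratified structure.

Three generators:

* :func:`random_uniform_hypergraph` — m distinct size-k hyperedges drawn
  uniformly from all C(n, k) possibilities; the null model with no planted
  structure (degree assortativity ~ 0 in expectation).
* :func:`planted_partition_hypergraph` — each hyperedge is, with probability
  ``p_in``, drawn entirely from one community (chosen with probability
  proportional to community size, so per-node edge exposure stays roughly
  uniform); otherwise drawn uniformly from all nodes.
* :func:`size_stratified_hypergraph` — the headline construction: small
  hyperedges (size <= k0) carry one planted partition, large hyperedges
  (size > k0) carry a *different* one.  Filtering by size then recovers two
  distinct community structures that no single whole-hypergraph clustering
  can match simultaneously.

All generators are deterministic given their seed, draw distinct hyperedges
by rejection sampling (exact edge counts), and produce hypergraphs that pass
preprocessing unchanged whenever the size spectrum excludes 1.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .hypergraph import Hypergraph


@dataclass
class GeneratorSpec:
    """Parameters of a planted-partition / size-stratified hypergraph.

    ``edge_sizes`` maps hyperedge size -> number of edges of that size.
    With ``stratified=True`` a second partition with ``c_large`` communities
    is planted on edges of size > ``k0``; otherwise a single partition with
    ``c`` communities covers all sizes.  ``p_in`` in [0, 1] is the
    probability that an edge is drawn within one community.
    """

    n: int
    edge_sizes: Mapping[int, int]
    c: int = 2
    p_in: float = 1.0
    seed: int = 0
    stratified: bool = False
    k0: int | None = None
    c_large: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.edge_sizes or sum(self.edge_sizes.values()) < 1:
            raise ValueError("edge_sizes must request at least one edge")
        if any(s < 1 or s > self.n for s in self.edge_sizes):
            raise ValueError("edge sizes must lie in 1..n")
        if not 0.0 <= self.p_in <= 1.0:
            raise ValueError("p_in must lie in [0, 1]")
        if self.stratified:
            sizes = sorted(self.edge_sizes)
            if self.k0 is None:
                raise ValueError("stratified spec requires the size threshold k0")
            if not sizes[0] <= self.k0 < sizes[-1]:
                raise ValueError(
                    f"k0={self.k0} must split the size spectrum {sizes}"
                )

    # -- plain-text round trip (key-value config) -------------------------

    def to_file(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"n = {self.n}\n")
            fh.write(
                "edge_sizes = "
                + ",".join(f"{s}:{m}" for s, m in sorted(self.edge_sizes.items()))
                + "\n"
            )
            fh.write(f"c = {self.c}\n")
            fh.write(f"p_in = {self.p_in}\n")
            fh.write(f"seed = {self.seed}\n")
            fh.write(f"stratified = {self.stratified}\n")
            if self.k0 is not None:
                fh.write(f"k0 = {self.k0}\n")
            if self.c_large is not None:
                fh.write(f"c_large = {self.c_large}\n")

    @classmethod
    def from_file(cls, path: str) -> "GeneratorSpec":
        kv: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                kv[key.strip()] = val.strip()
        sizes = {
            int(s): int(m)
            for s, m in (pair.split(":") for pair in kv["edge_sizes"].split(","))
        }
        return cls(
            n=int(kv["n"]),
            edge_sizes=sizes,
            c=int(kv.get("c", 2)),
            p_in=float(kv.get("p_in", 1.0)),
            seed=int(kv.get("seed", 0)),
            stratified=kv.get("stratified", "False") == "True",
            k0=int(kv["k0"]) if "k0" in kv else None,
            c_large=int(kv["c_large"]) if "c_large" in kv else None,
        )


def write_labels(path: str, labels: Mapping) -> None:
    """Ground-truth labels as two-column CSV (node, label)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["node", "label"])
        for v, l in labels.items():
            writer.writerow([v, l])


def _draw_distinct_edges(
    rng: np.random.Generator,
    pool_of: "callable",
    sizes: Sequence[int],
    existing: set[frozenset] | None = None,
    max_tries: int = 10_000,
) -> list[frozenset]:
    """Rejection-sample distinct hyperedges; pool_of(size) -> candidate pool."""
    seen: set[frozenset] = set() if existing is None else existing
    edges: list[frozenset] = []
    for s in sizes:
        for _ in range(max_tries):
            pool = pool_of(s)
            e = frozenset(rng.choice(pool, size=s, replace=False).tolist())
            if e not in seen:
                seen.add(e)
                edges.append(e)
                break
        else:
            raise RuntimeError(
                f"could not draw a distinct size-{s} edge after {max_tries} tries"
            )
    return edges


def random_uniform_hypergraph(n: int, m: int, k: int, seed: int = 0) -> Hypergraph:
    """m distinct size-k hyperedges uniform over all C(n, k) possibilities."""
    if k > n:
        raise ValueError(f"edge size k={k} exceeds n={n}")
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > math.comb(n, k):
        raise ValueError(f"m={m} exceeds C({n},{k})={math.comb(n, k)}")
    rng = np.random.default_rng(seed)
    all_nodes = np.arange(n)
    edges = _draw_distinct_edges(rng, lambda s: all_nodes, [k] * m)
    return Hypergraph(range(n), edges, name=f"uniform(n={n},m={m},k={k})")


def _planted_edges(
    rng: np.random.Generator,
    labels: np.ndarray,
    sizes: Sequence[int],
    p_in: float,
    seen: set[frozenset],
) -> list[frozenset]:
    n = len(labels)
    communities = {c: np.flatnonzero(labels == c) for c in np.unique(labels)}
    comm_ids = sorted(communities)
    weights = np.array([len(communities[c]) for c in comm_ids], dtype=float)
    weights /= weights.sum()
    all_nodes = np.arange(n)

    def pool_of_factory(s: int) -> np.ndarray:
        if rng.random() < p_in:
            feasible = [c for c in comm_ids if len(communities[c]) >= s]
            if not feasible:
                raise ValueError(
                    f"no community large enough for a size-{s} edge with p_in > 0"
                )
            w = np.array([len(communities[c]) for c in feasible], dtype=float)
            w /= w.sum()
            return communities[feasible[rng.choice(len(feasible), p=w)]]
        return all_nodes

    return _draw_distinct_edges(rng, pool_of_factory, sizes, existing=seen)


def _balanced_labels(n: int, c: int) -> np.ndarray:
    # contiguous blocks: nodes 0..n/c-1 in community 0, etc.
    return np.repeat(np.arange(c), [(n + i) // c for i in range(c)][::-1])[:n]


def planted_partition_hypergraph(
    spec: GeneratorSpec | None = None,
    *,
    n: int | None = None,
    edge_sizes: Mapping[int, int] | None = None,
    c: int = 2,
    p_in: float = 1.0,
    seed: int = 0,
    labels: Sequence[int] | None = None,
) -> tuple[Hypergraph, dict]:
    """Hypergraph with one planted partition; returns (H, ground-truth labels).

    Each requested edge is within-community with probability ``p_in``
    (community chosen proportional to size) and uniform over all nodes
    otherwise.  ``p_in = 0`` reduces to size-wise uniform sampling;
    ``c = 1`` plants the trivial all-equal labeling.
    """
    if spec is None:
        spec = GeneratorSpec(n=n, edge_sizes=dict(edge_sizes), c=c, p_in=p_in, seed=seed)
    rng = np.random.default_rng(spec.seed)
    lab = (
        np.asarray(labels, dtype=int)
        if labels is not None
        else _balanced_labels(spec.n, spec.c)
    )
    sizes = [s for s in sorted(spec.edge_sizes) for _ in range(spec.edge_sizes[s])]
    edges = _planted_edges(rng, lab, sizes, spec.p_in, set())
    H = Hypergraph(range(spec.n), edges, name="planted_partition")
    return H, {v: int(lab[v]) for v in range(spec.n)}


# defaults for the size-stratified experiment: 64 nodes, two partitions that
# cut across each other (halves vs. recombined quarters), dyads+triads on the
# small stratum, 5- and 6-edges on the large stratum, fully biased edges
STRATIFIED_DEFAULTS = dict(
    n=64,
    sizes_small={2: 80, 3: 60},
    sizes_large={5: 40, 6: 30},
    p_in=1.0,
)


def _crosscut_labels(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Two bipartitions with 50% overlap: halves vs. recombined quarters."""
    a = (np.arange(n) >= n // 2).astype(int)
    q = np.arange(n) * 4 // n
    b = np.isin(q, (1, 2)).astype(int)  # quarters 2+3 vs 1+4
    return a, b


def size_stratified_hypergraph(
    n: int | None = None,
    sizes_small: Mapping[int, int] | None = None,
    sizes_large: Mapping[int, int] | None = None,
    p_in: float | None = None,
    seed: int = 0,
    labels_small: Sequence[int] | None = None,
    labels_large: Sequence[int] | None = None,
) -> tuple[Hypergraph, dict, dict]:
    """Hypergraph whose community structure differs by hyperedge size.

    Edges with sizes from ``sizes_small`` are planted on partition A
    (``labels_small``), edges from ``sizes_large`` on partition B
    (``labels_large``).  Defaults plant two crosscutting bipartitions of 64
    nodes with fully within-community edges, so a LEQ filtering at the size
    threshold recovers A and a GEQ filtering recovers B, while clustering the
    whole hypergraph cannot match both.

    Returns ``(H, labels_A, labels_B)`` with labels as node -> int dicts.
    """
    n = STRATIFIED_DEFAULTS["n"] if n is None else n
    sizes_small = dict(
        STRATIFIED_DEFAULTS["sizes_small"] if sizes_small is None else sizes_small
    )
    sizes_large = dict(
        STRATIFIED_DEFAULTS["sizes_large"] if sizes_large is None else sizes_large
    )
    p_in = STRATIFIED_DEFAULTS["p_in"] if p_in is None else p_in
    if max(sizes_small) >= min(sizes_large):
        raise ValueError("small-stratum sizes must all be below large-stratum sizes")
    if labels_small is None or labels_large is None:
        a, b = _crosscut_labels(n)
        lab_a = a if labels_small is None else np.asarray(labels_small, dtype=int)
        lab_b = b if labels_large is None else np.asarray(labels_large, dtype=int)
    else:
        lab_a = np.asarray(labels_small, dtype=int)
        lab_b = np.asarray(labels_large, dtype=int)
    rng = np.random.default_rng(seed)
    seen: set[frozenset] = set()
    small = [s for s in sorted(sizes_small) for _ in range(sizes_small[s])]
    large = [s for s in sorted(sizes_large) for _ in range(sizes_large[s])]
    edges = _planted_edges(rng, lab_a, small, p_in, seen)
    edges += _planted_edges(rng, lab_b, large, p_in, seen)
    H = Hypergraph(range(n), edges, name="size_stratified")
    return (
        H,
        {v: int(lab_a[v]) for v in range(n)},
        {v: int(lab_b[v]) for v in range(n)},
    )


def generate_from_spec(spec: GeneratorSpec):
    """Dispatch on ``spec.stratified``; used by the CLI's generate command."""
    if not spec.stratified:
        return planted_partition_hypergraph(spec)
    sizes_small = {s: m for s, m in spec.edge_sizes.items() if s <= spec.k0}
    sizes_large = {s: m for s, m in spec.edge_sizes.items() if s > spec.k0}
    n = spec.n
    lab_a = _balanced_labels(n, spec.c)
    lab_b = _balanced_labels(n, spec.c_large or spec.c)
    # rotate partition B by a quarter so the two partitions crosscut
    lab_b = np.roll(lab_b, n // 4)
    return size_stratified_hypergraph(
        n=n,
        sizes_small=sizes_small,
        sizes_large=sizes_large,
        p_in=spec.p_in,
        seed=spec.seed,
        labels_small=lab_a,
        labels_large=lab_b,
    )
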