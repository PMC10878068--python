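"""Size-dependent filtering of hypergraphs.

A size filter keeps the hyperedges whose size compares to a filtering
parameter ``k`` under one of four operators:

* ``eq``  — uniform filtering: only size-k edges (isolates one scale).
* ``geq`` — "higher-order" filtering: edges of size >= k (drops small ones).
* ``leq`` — "lower-order" filtering: edges of size <= k (drops large ones).
* ``neq`` — exclusion filtering: everything except size-k edges.

Every filtering retains the full node set of the parent hypergraph (node
filter identically 1), so nodal measures stay comparable across filterings;
nodes whose edges were all removed become isolated in the filtering.
"""

from __future__ import annotations

import operator
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .hypergraph import Hypergraph

_OPS = {
    "eq": operator.eq,
    "geq": operator.ge,
    "leq": operator.le,
    "neq": operator.ne,
}

FILTER_OPS = tuple(_OPS)


@dataclass(frozen=True)
class SizeFilter:
    """A comparison operator and a positive integer filtering parameter."""

    op: str
    k: int

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}; expected one of {FILTER_OPS}")
        if self.k < 1:
            raise ValueError(f"filtering parameter must be >= 1, got {self.k}")

    def keeps(self, size: int) -> bool:
        return _OPS[self.op](size, self.k)

    def designation(self) -> str:
        """Compact string form used by the CLI, e.g. ``'geq5'``."""
        return f"{self.op}{self.k}"

    @classmethod
    def parse(cls, text: str) -> "SizeFilter":
        m = re.fullmatch(r"(eq|geq|leq|neq)(\d+)", text.strip())
        if m is None:
            raise ValueError(
                f"cannot parse filter designation {text!r}; expected e.g. 'geq5'"
            )
        return cls(m.group(1), int(m.group(2)))


@dataclass
class FilteringSet:
    """A base hypergraph together with a list of its size filterings.

    Every member shares the base node set; only edge lists differ.
    """

    base: Hypergraph
    members: list[tuple[SizeFilter, Hypergraph]]

    def filters(self) -> list[SizeFilter]:
        return [f for f, _ in self.members]

    def hypergraphs(self) -> list[Hypergraph]:
        return [h for _, h in self.members]


def size_filter(H: Hypergraph, filt: SizeFilter | str, k: int | None = None) -> Hypergraph:
    """Apply a size filter, keeping all nodes and the matching edges in order.

    Accepts either a :class:`SizeFilter` or an operator name plus ``k``
    (``size_filter(H, "geq", 3)``).  An empty edge result is legal.
    """
    if isinstance(filt, str):
        if k is None:
            filt = SizeFilter.parse(filt)
        else:
            filt = SizeFilter(filt, k)
    kept = [e for e in H.edges if filt.keeps(len(e))]
    name = f"{H.name}[{filt.designation()}]" if H.name else None
    return Hypergraph(H.nodes, kept, name=name)


def filtering_set(H: Hypergraph, op: str, K: Sequence[int]) -> FilteringSet:
    """One filtering per k in ``K``, all under the same operator."""
    if not K:
        raise ValueError("K must be non-empty")
    members = [(SizeFilter(op, k), size_filter(H, SizeFilter(op, k))) for k in K]
    return FilteringSet(base=H, members=members)


def is_disjoint(FS: FilteringSet) -> bool:
    """True iff member edge multisets are pairwise disjoint.

    The full uniform filtering set is disjoint; LEQ/GEQ/exclusion sets
    generally overlap.  Multiplicity is respected: an edge occurring twice in
    the base may occur at most twice across all members combined for the set
    to count as disjoint.
    """
    from collections import Counter

    total: Counter = Counter()
    for _, Hk in FS.members:
        total.update(Hk.edges)
    base = Counter(FS.base.edges)
    return all(total[e] <= base[e] for e in total)


def union_filterings(FS: FilteringSet) -> Hypergraph:
    """Edge-wise union of the member filterings, node-wise union.

    Multiset union: an edge's multiplicity in the result is its largest
    multiplicity in any single member, so overlapping members are not double
    counted while multi-edges within one member survive.  With the full
    uniform (or exclusion, given >= 2 distinct sizes) set this reconstructs
    the base hypergraph exactly.
    """
    from collections import Counter

    nodes: dict = {}
    for _, Hk in FS.members:
        for v in Hk.nodes:
            nodes.setdefault(v)
    mult: Counter = Counter()
    order: list = []
    for _, Hk in FS.members:
        member_counts = Counter(Hk.edges)
        for e, m in member_counts.items():
            if e not in mult:
                order.append(e)
            mult[e] = max(mult[e], m)
    edges = [e for e in order for _ in range(mult[e])]
    return Hypergraph(tuple(nodes), edges, name=FS.base.name)


def sweep_k_range(H: Hypergraph, kmin: int | None = None, kmax: int | None = None) -> range:
    """Default filtering-parameter range: 2 .. max edge size.

    Singleton edges are removed during preprocessing, so sweeps start at 2
    unless told otherwise.
    """
    sizes = H.edge_sizes()
    if not sizes:
        return range(0)
    lo = 2 if kmin is None else kmin
    hi = max(sizes) if kmax is None else kmax
    return range(lo, hi + 1)
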