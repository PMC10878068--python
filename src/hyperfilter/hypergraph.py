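"""Hypergraph data model and basic structural summaries.

A hypergraph is a pair ``(V, E)`` where each hyperedge is a non-empty set of
node labels.  Nodes may be isolated (a member of ``V`` that occurs in no
edge): size-dependent filtering keeps the full node set of the parent
hypergraph in every filtering, so isolated nodes are first-class citizens
here.  Edge multiplicity is allowed at the container level; :func:`preprocess`
removes it.

Node labels are opaque (strings or integers).  Matrix-producing operations
maintain an internal contiguous 0-based index; user-facing outputs always use
the original labels.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

Label = Hashable


class Hypergraph:
    """An ordered node set plus an ordered list of hyperedges.

    Parameters
    ----------
    nodes
        Node labels.  Order is preserved; duplicates are collapsed.  Labels
        appearing in ``edges`` but not listed here are appended in
        first-appearance order.
    edges
        Iterables of node labels, one per hyperedge.  Within-edge duplicate
        labels are collapsed (edges are sets) with a logged warning.
        Duplicate edges (multi-edges) are preserved.
    name
        Optional dataset name carried through I/O.
    """

    def __init__(
        self,
        nodes: Iterable[Label] = (),
        edges: Iterable[Iterable[Label]] = (),
        name: str | None = None,
    ) -> None:
        seen: dict[Label, None] = {}
        for v in nodes:
            seen.setdefault(v)
        edge_list: list[frozenset[Label]] = []
        for i, e in enumerate(edges):
            members = list(e)
            fs = frozenset(members)
            if not fs:
                raise ValueError(f"edge {i} is empty; hyperedges must be non-empty")
            if len(fs) < len(members):
                logger.warning(
                    "edge %d contains repeated node labels; collapsed to %d members",
                    i,
                    len(fs),
                )
            for v in members:
                seen.setdefault(v)
            edge_list.append(fs)
        self._nodes: tuple[Label, ...] = tuple(seen)
        self._edges: tuple[frozenset[Label], ...] = tuple(edge_list)
        self._index: dict[Label, int] = {v: i for i, v in enumerate(self._nodes)}
        self.name = name

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[Label, ...]:
        return self._nodes

    @property
    def edges(self) -> tuple[frozenset[Label], ...]:
        return self._edges

    @property
    def num_nodes(self) -> int:
        return len(self._nodes)

    @property
    def num_edges(self) -> int:
        return len(self._edges)

    def node_index(self) -> dict[Label, int]:
        """Stable label -> contiguous 0-based index map."""
        return dict(self._index)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        label = f" {self.name!r}" if self.name else ""
        return f"<Hypergraph{label}: {self.num_nodes} nodes, {self.num_edges} edges>"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Hypergraph):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and Counter(
            self._edges
        ) == Counter(other._edges)

    __hash__ = None  # type: ignore[assignment]

    # -- summaries ---------------------------------------------------------

    def degrees(self) -> dict[Label, int]:
        """Node degree = number of hyperedges containing the node.

        Isolated nodes get degree 0.  The handshake identity
        ``sum(degrees) == sum(edge sizes)`` holds by construction.
        """
        deg = {v: 0 for v in self._nodes}
        for e in self._edges:
            for v in e:
                deg[v] += 1
        return deg

    def edge_size_distribution(self) -> dict[int, int]:
        """Map hyperedge size -> number of edges of that size."""
        return dict(Counter(len(e) for e in self._edges))

    def edge_sizes(self) -> list[int]:
        return [len(e) for e in self._edges]

    def isolated_nodes(self) -> list[Label]:
        deg = self.degrees()
        return [v for v in self._nodes if deg[v] == 0]

    def incidence_matrix(self, nodes: Sequence[Label] | None = None) -> sp.csr_array:
        """Sparse node-by-edge 0/1 incidence matrix B.

        Rows follow ``nodes`` (default: all nodes in container order).
        """
        if nodes is None:
            nodes = self._nodes
        idx = {v: i for i, v in enumerate(nodes)}
        rows, cols = [], []
        for j, e in enumerate(self._edges):
            for v in e:
                if v in idx:
                    rows.append(idx[v])
                    cols.append(j)
        data = np.ones(len(rows))
        return sp.csr_array(
            (data, (rows, cols)), shape=(len(nodes), self.num_edges)
        )


@dataclass
class WeightedProjection:
    """Clique projection of a hypergraph onto its non-isolated nodes.

    ``weights[i, j]`` counts the hyperedges containing both node ``i`` and
    node ``j`` (co-membership multiplicity); the diagonal is zero.  Row sums
    are strictly positive for every included node whenever the hypergraph has
    an edge of size >= 2 through that node.
    """

    nodes: tuple[Label, ...]
    weights: sp.csr_array
    binarized: bool = False
    _index: dict[Label, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.nodes)}

    @property
    def num_nodes(self) -> int:
        return len(self.nodes)

    def dense(self) -> np.ndarray:
        return self.weights.toarray()

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic matrix of l1-normalized projection rows W_i^out."""
        W = self.dense().astype(float)
        row_sums = W.sum(axis=1, keepdims=True)
        if np.any(row_sums == 0):
            raise ValueError("projection contains a zero row; node has no neighbours")
        return W / row_sums


def clique_projection(H: Hypergraph, binarize: bool = False) -> WeightedProjection:
    """Weighted pairwise projection: w(i, j) = #edges containing both i and j.

    Isolated nodes (including nodes only in singleton edges) are excluded.
    With ``binarize=True`` the weights are clipped to 0/1.

    Raises
    ------
    ValueError
        If no edge of size >= 2 exists, so the projection would be empty.
    """
    # preserve container node order among nodes touched by a size>=2 edge
    touched = set()
    for e in H.edges:
        if len(e) >= 2:
            touched.update(e)
    if not touched:
        raise ValueError("hypergraph has no edge of size >= 2; projection is empty")
    nodes = tuple(v for v in H.nodes if v in touched)
    B = H.incidence_matrix(nodes)
    # only size>=2 edges contribute off-diagonal weight; size-1 columns add
    # nothing off the diagonal, which we zero anyway
    W = (B @ B.T).tocsr()
    W.setdiag(0)
    W.eliminate_zeros()
    if binarize:
        W.data = np.minimum(W.data, 1.0)
    return WeightedProjection(nodes=nodes, weights=sp.csr_array(W), binarized=binarize)


def preprocess(H: Hypergraph) -> Hypergraph:
    """Remove multi-edges, singleton edges and then isolated nodes.

    Order: deduplicate edges (set equality of membership, keeping the first
    occurrence), drop edges of size 1, drop nodes left with degree 0.  The
    operation is idempotent and preserves the relative order of survivors.

    Raises
    ------
    ValueError
        If no edge survives.
    """
    seen_edges: set[frozenset[Label]] = set()
    kept: list[frozenset[Label]] = []
    n_dupes = n_singletons = 0
    for e in H.edges:
        if e in seen_edges:
            n_dupes += 1
            continue
        seen_edges.add(e)
        if len(e) < 2:
            n_singletons += 1
            continue
        kept.append(e)
    if not kept:
        raise ValueError("empty after preprocessing: no edge of size >= 2 survives")
    covered = set().union(*kept)
    nodes = [v for v in H.nodes if v in covered]
    n_isolated = H.num_nodes - len(nodes)
    if n_dupes or n_singletons or n_isolated:
        logger.info(
            "preprocess removed %d multi-edges, %d singleton edges, %d isolated nodes",
            n_dupes,
            n_singletons,
            n_isolated,
        )
    return Hypergraph(nodes, kept, name=H.name)


def connected_components(H: Hypergraph) -> list[set[Label]]:
    """Connected components over non-isolated nodes.

    Two nodes are connected when they share a hyperedge.  Isolated nodes are
    not reported.
    """
    parent: dict[Label, Label] = {}

    def find(v: Label) -> Label:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    def union(u: Label, v: Label) -> None:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[rv] = ru

    for e in H.edges:
        members = list(e)
        for v in members:
            parent.setdefault(v, v)
        for v in members[1:]:
            union(members[0], v)
    comps: dict[Label, set[Label]] = {}
    for v in parent:
        comps.setdefault(find(v), set()).add(v)
    return list(comps.values())
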