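"""Per-node measures: betweenness centrality and spectral community detection.

Betweenness generalizes to hypergraphs through node-based shortest paths:
consecutive nodes on a path must share at least one hyperedge, i.e. paths are
unweighted shortest paths on the *binarized* clique projection (the weighted
projection is deliberately not used for distances).  ``BC(n)`` sums
``sigma_uv(n) / sigma_uv`` over unordered pairs ``u != v != n``; pairs in
different components contribute nothing, so disconnected filterings need no
special handling.

Community detection follows the spectral method on the normalized hypergraph
Laplacian

    L = I - D_v^{-1/2} B D_e^{-1} B^T D_v^{-1/2},

with ``B`` the node-edge incidence matrix of the non-isolated nodes, ``D_v``
node degrees, ``D_e`` edge sizes and unit edge weights.  The eigenvectors of
the ``c`` smallest eigenvalues are clustered with k-means.  Nodes isolated in
the filtering receive the sentinel label -1.

Labelings from different filterings are aligned with Hungarian matching on
the confusion matrix so that community indices are comparable across
filtering parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .hypergraph import Hypergraph, connected_components

logger = logging.getLogger(__name__)

Label = Hashable

UNASSIGNED = -1

# below this many active nodes the Laplacian eigenproblem is solved densely;
# Lanczos iteration is reserved for genuinely large filterings
_DENSE_EIG_LIMIT = 500


@dataclass
class CentralityVector:
    """node -> betweenness value, with the conventions used to compute it."""

    values: dict[Label, float]
    normalized: bool = False
    component_handling: str = "per_component"

    def __getitem__(self, v: Label) -> float:
        return self.values[v]

    def as_dict(self) -> dict[Label, float]:
        return dict(self.values)

    def top(self, n: int = 10) -> list[tuple[Label, float]]:
        return sorted(self.values.items(), key=lambda kv: (-kv[1], str(kv[0])))[:n]


@dataclass
class CommunityLabeling:
    """node -> integer community label; -1 marks unassignable (isolated) nodes."""

    labels: dict[Label, int]
    c: int
    seed: int | None = None

    def __getitem__(self, v: Label) -> int:
        return self.labels[v]

    def as_dict(self) -> dict[Label, int]:
        return dict(self.labels)

    def assigned_nodes(self) -> list[Label]:
        return [v for v, l in self.labels.items() if l != UNASSIGNED]


def projection_graph(H: Hypergraph) -> nx.Graph:
    """Binarized clique projection as a networkx graph (all nodes included)."""
    G = nx.Graph()
    G.add_nodes_from(H.nodes)
    for e in H.edges:
        members = sorted(e, key=str)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                G.add_edge(members[i], members[j])
    return G


def betweenness_centrality(H: Hypergraph, normalized: bool = False) -> CentralityVector:
    """Node betweenness via Brandes' algorithm on the clique projection.

    Unnormalized by default.  With ``normalized=True`` each node's value is
    divided by ``(N - 1)(N - 2) / 2`` where ``N`` is the size of the node's
    connected component (nodes in components of size < 3 get 0).  Nodes
    isolated in the filtering always score 0.
    """
    G = projection_graph(H)
    raw = nx.betweenness_centrality(G, normalized=False)
    values = {v: float(raw.get(v, 0.0)) for v in H.nodes}
    if normalized:
        for comp in connected_components(H):
            N = len(comp)
            denom = (N - 1) * (N - 2) / 2
            for v in comp:
                values[v] = values[v] / denom if denom > 0 else 0.0
    return CentralityVector(values=values, normalized=normalized)


def hypergraph_laplacian(H: Hypergraph) -> tuple[sp.csr_array, tuple[Label, ...]]:
    """Normalized hypergraph Laplacian over non-isolated nodes.

    Returns the sparse symmetric operator and the node order of its rows.
    Eigenvalues lie in [0, 2]; the multiplicity of eigenvalue 0 equals the
    number of connected components.
    """
    deg = H.degrees()
    active = tuple(v for v in H.nodes if deg[v] > 0)
    if not active:
        raise ValueError("hypergraph has no non-isolated nodes")
    B = H.incidence_matrix(active)
    dv = np.array([deg[v] for v in active], dtype=float)
    de = np.array(H.edge_sizes(), dtype=float)
    Dv_isqrt = sp.diags_array(1.0 / np.sqrt(dv))
    De_inv = sp.diags_array(1.0 / de)
    theta = Dv_isqrt @ B @ De_inv @ B.T @ Dv_isqrt
    L = sp.eye_array(len(active), format="csr") - theta
    return sp.csr_array(L), active


def _fix_eigenvector_signs(U: np.ndarray) -> np.ndarray:
    # deterministic sign convention: largest-magnitude entry positive
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return U


def spectral_embedding(H: Hypergraph, c: int) -> tuple[np.ndarray, tuple[Label, ...]]:
    """Eigenvectors of the ``c`` smallest Laplacian eigenvalues, sign-fixed."""
    L, active = hypergraph_laplacian(H)
    n = len(active)
    if c > n:
        raise ValueError(f"requested {c} communities but only {n} non-isolated nodes")
    if n < _DENSE_EIG_LIMIT or c >= n - 1:
        w, U = np.linalg.eigh(L.toarray())
        U = U[:, :c]
    else:
        w, U = spla.eigsh(L, k=c, sigma=-1e-3, which="LM", tol=1e-9)
        order = np.argsort(w)
        U = U[:, order]
    return _fix_eigenvector_signs(np.ascontiguousarray(U)), active


def spectral_communities(H: Hypergraph, c: int, seed: int = 0) -> CommunityLabeling:
    """Spectral clustering on the normalized hypergraph Laplacian.

    Deterministic given ``(H, c, seed)``: the eigenvector signs are fixed and
    k-means runs 20 seeded restarts, keeping the best inertia.  Nodes
    isolated in the filtering receive the sentinel -1.
    """
    if c < 2:
        raise ValueError("c must be >= 2")
    U, active = spectral_embedding(H, c)
    km = KMeans(n_clusters=c, n_init=20, random_state=seed)
    assigned = km.fit_predict(U)
    labels = {v: UNASSIGNED for v in H.nodes}
    for v, l in zip(active, assigned):
        labels[v] = int(l)
    return CommunityLabeling(labels=labels, c=c, seed=seed)


def match_labels(
    reference: CommunityLabeling, other: CommunityLabeling
) -> tuple[CommunityLabeling, float]:
    """Align ``other``'s labels to ``reference`` by Hungarian matching.

    Builds the confusion matrix over nodes assigned in both labelings, solves
    the assignment problem maximizing total overlap, and relabels ``other``
    accordingly; labels of ``other`` left unmatched keep fresh indices.
    Returns the relabeled copy and the agreement = matched overlap / number
    of co-labeled nodes (NaN if no node is assigned in both).
    """
    if set(reference.labels) != set(other.labels):
        raise ValueError("labelings must cover the same node set")
    common = [
        v
        for v in reference.labels
        if reference[v] != UNASSIGNED and other[v] != UNASSIGNED
    ]
    if not common:
        return CommunityLabeling(other.as_dict(), c=other.c, seed=other.seed), float("nan")
    ref_ids = sorted({reference[v] for v in common})
    oth_ids = sorted({other[v] for v in common} | {l for l in other.labels.values() if l != UNASSIGNED})
    ref_pos = {l: i for i, l in enumerate(ref_ids)}
    oth_pos = {l: i for i, l in enumerate(oth_ids)}
    conf = np.zeros((len(ref_ids), len(oth_ids)))
    for v in common:
        conf[ref_pos[reference[v]], oth_pos[other[v]]] += 1
    rows, cols = linear_sum_assignment(conf, maximize=True)
    mapping = {oth_ids[j]: ref_ids[i] for i, j in zip(rows, cols)}
    overlap = conf[rows, cols].sum()
    # unmatched labels of `other` get fresh indices beyond every used label
    fresh = max(ref_ids + list(mapping.values()), default=-1) + 1
    for l in oth_ids:
        if l not in mapping:
            mapping[l] = fresh
            fresh += 1
    relabeled = {
        v: (mapping[l] if l != UNASSIGNED else UNASSIGNED)
        for v, l in other.labels.items()
    }
    agreement = float(overlap) / len(common)
    return CommunityLabeling(relabeled, c=other.c, seed=other.seed), agreement
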