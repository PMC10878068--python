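"""Global structural measures of a (filtered) hypergraph.

Effective information (EI)
    Defined on the weighted clique projection.  With ``W_i_out`` the
    l1-normalized row of co-membership weights for node ``i`` (its
    out-transition distribution under a random walk) and ``H`` the Shannon
    entropy in bits,

        EI = H(<W_i_out>) - <H(W_i_out)>,

    averaging over the projection's (non-isolated) nodes.  EI quantifies the
    strength of unique associations: it is 0 when every node's neighbourhood
    distribution looks the same and approaches ``log2(n)`` when each node
    points somewhere different.  The normalized variant divides by
    ``log2(n_active)``, the maximum achievable entropy of the mean
    distribution, mapping EI to [0, 1].

Dynamical assortativity (rho)
    A degree-correlation measure over within-hyperedge node pairs,

        rho = <k>^2 <k k1>_E / <k^2>^2 - 1,

    where ``<k^r>`` are degree moments over non-isolated nodes and
    ``<k k1>_E`` is the expected pairwise product of degrees over hyperedges.
    rho = 0 exactly for degree-regular hypergraphs.

Pearson degree assortativity (top-bottom / top-2 / uniform)
    Per hyperedge, select degree pairs by a rule — (max, min) degree;
    the two largest degrees; or every unordered distinct pair — then report
    the Pearson correlation of the pooled observations, symmetrized by
    including each pair in both orders.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .hypergraph import Hypergraph, clique_projection

logger = logging.getLogger(__name__)

ASSORTATIVITY_RULES = ("top_bottom", "top_2", "uniform")


@dataclass
class GlobalMetricResult:
    """A named global metric value with the context it was computed in.

    ``value`` is NaN exactly when the metric's preconditions fail (no
    qualifying edges, zero degree variance, ...); ``defined`` mirrors that.
    """

    metric: str
    value: float
    n_edges: int
    n_active_nodes: int
    normalized: bool = False

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def _undefined(metric: str, H: Hypergraph, normalized: bool = False) -> GlobalMetricResult:
    return GlobalMetricResult(
        metric=metric,
        value=float("nan"),
        n_edges=H.num_edges,
        n_active_nodes=0,
        normalized=normalized,
    )


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def effective_information(H: Hypergraph, normalized: bool = False) -> GlobalMetricResult:
    """EI of the hypergraph's weighted clique projection, in bits.

    Undefined (NaN) when the hypergraph has no edge of size >= 2 — e.g. a
    uniform filtering at a size absent from the dataset.
    """
    metric = "ei_norm" if normalized else "ei"
    try:
        proj = clique_projection(H)
    except ValueError:
        return _undefined(metric, H, normalized)
    P = proj.transition_matrix()
    mean_out = P.mean(axis=0)
    ei = _entropy_bits(mean_out) - float(
        np.mean([_entropy_bits(row) for row in P])
    )
    if normalized:
        n = proj.num_nodes
        ei = ei / math.log2(n) if n > 1 else float("nan")
    return GlobalMetricResult(
        metric=metric,
        value=ei,
        n_edges=H.num_edges,
        n_active_nodes=proj.num_nodes,
        normalized=normalized,
    )


def dynamical_assortativity(
    H: Hypergraph, pair_weighting: str = "per_edge"
) -> GlobalMetricResult:
    """rho = <k>^2 <k k1>_E / <k^2>^2 - 1 over within-edge degree pairs.

    Degree moments run over non-isolated nodes.  ``pair_weighting`` fixes how
    ``<k k1>_E`` averages the per-pair degree products: ``"per_edge"``
    (default) takes the mean over pairs within each edge and then the mean
    over edges, so each hyperedge contributes equally regardless of its size;
    ``"pooled"`` averages over all (edge, pair) observations directly.
    """
    if pair_weighting not in ("per_edge", "pooled"):
        raise ValueError(f"unknown pair_weighting {pair_weighting!r}")
    deg = H.degrees()
    pair_edges = [e for e in H.edges if len(e) >= 2]
    if not pair_edges:
        return _undefined("rho_dyn", H)
    active = [v for v in H.nodes if deg[v] > 0]
    k = np.array([deg[v] for v in active], dtype=float)
    k1, k2 = k.mean(), (k**2).mean()
    per_edge_means = []
    pooled = []
    for e in pair_edges:
        prods = [deg[u] * deg[v] for u, v in itertools.combinations(sorted(e, key=str), 2)]
        per_edge_means.append(float(np.mean(prods)))
        pooled.extend(prods)
    kk1 = (
        float(np.mean(per_edge_means))
        if pair_weighting == "per_edge"
        else float(np.mean(pooled))
    )
    rho = (k1**2) * kk1 / (k2**2) - 1.0
    return GlobalMetricResult(
        metric="rho_dyn", value=rho, n_edges=H.num_edges, n_active_nodes=len(active)
    )


def _degree_pairs(H: Hypergraph, rule: str, degree_mode: str) -> list[tuple[float, float]]:
    deg = H.degrees()
    shift = 1 if degree_mode == "excess" else 0
    obs: list[tuple[float, float]] = []
    for e in H.edges:
        if len(e) < 2:
            continue
        # sorted degree values; top-2 ties resolve identically either way
        ds = sorted(deg[v] - shift for v in e)
        if rule == "top_bottom":
            obs.append((float(ds[-1]), float(ds[0])))
        elif rule == "top_2":
            obs.append((float(ds[-1]), float(ds[-2])))
        elif rule == "uniform":
            for a, b in itertools.combinations(ds, 2):
                obs.append((float(a), float(b)))
        else:
            raise ValueError(
                f"unknown rule {rule!r}; expected one of {ASSORTATIVITY_RULES}"
            )
    return obs


def pearson_degree_assortativity(
    H: Hypergraph, rule: str = "uniform", degree_mode: str = "full"
) -> GlobalMetricResult:
    """Pearson correlation of within-edge degree pairs under a selection rule.

    Observations are symmetrized (each pair enters in both orders), so the
    result is invariant to within-pair order.  ``degree_mode="excess"``
    subtracts 1 from every degree first; it shifts both coordinates equally
    and leaves the correlation unchanged, but is exposed for parity with
    selection-rule formulations that use remaining degree.

    NaN (logged) when either coordinate has zero variance, e.g. on
    degree-regular hypergraphs, or with fewer than two observations.
    """
    if degree_mode not in ("full", "excess"):
        raise ValueError(f"unknown degree_mode {degree_mode!r}")
    metric = f"assort_{'tb' if rule == 'top_bottom' else 't2' if rule == 'top_2' else 'unif'}"
    obs = _degree_pairs(H, rule, degree_mode)
    if len(obs) < 2:
        return _undefined(metric, H)
    xs = np.array([p[0] for p in obs] + [p[1] for p in obs], dtype=float)
    ys = np.array([p[1] for p in obs] + [p[0] for p in obs], dtype=float)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        logger.info("assortativity %s undefined: zero degree variance", metric)
        return _undefined(metric, H)
    r = float(np.corrcoef(xs, ys)[0, 1])
    deg = H.degrees()
    active = sum(1 for v in H.nodes if deg[v] > 0)
    return GlobalMetricResult(
        metric=metric, value=r, n_edges=H.num_edges, n_active_nodes=active
    )
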