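"""Independent brute-force oracles used to validate the library's measures.

Everything here is written as directly as possible — double loops, explicit
BFS path counting, exhaustive permutation search — and deliberately shares no
code path with the implementations under test.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def brute_projection_weights(edges) -> dict[tuple, int]:
    """Pair -> co-membership count via a double loop over edges and pairs."""
    w: dict[tuple, int] = {}
    for e in edges:
        for u, v in itertools.combinations(sorted(e, key=str), 2):
            key = (u, v)
            w[key] = w.get(key, 0) + 1
    return w


def brute_degrees(nodes, edges) -> dict:
    return {v: sum(1 for e in edges if v in e) for v in nodes}


def brute_dynamical_assortativity(nodes, edges, pair_weighting="per_edge") -> float:
    deg = brute_degrees(nodes, edges)
    pair_edges = [e for e in edges if len(e) >= 2]
    active = [v for v in nodes if deg[v] > 0]
    k1 = sum(deg[v] for v in active) / len(active)
    k2 = sum(deg[v] ** 2 for v in active) / len(active)
    per_edge, pooled = [], []
    for e in pair_edges:
        prods = [deg[u] * deg[v] for u, v in itertools.combinations(list(e), 2)]
        per_edge.append(sum(prods) / len(prods))
        pooled.extend(prods)
    if pair_weighting == "per_edge":
        kk1 = sum(per_edge) / len(per_edge)
    else:
        kk1 = sum(pooled) / len(pooled)
    return k1**2 * kk1 / k2**2 - 1.0


def _pearson(xs, ys) -> float:
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    if vx == 0 or vy == 0:
        return float("nan")
    return cov / math.sqrt(vx * vy)


def brute_pearson_assortativity(nodes, edges, rule) -> float:
    """Pearson over symmetrized per-edge degree-pair observations."""
    deg = brute_degrees(nodes, edges)
    obs = []
    for e in edges:
        if len(e) < 2:
            continue
        ds = sorted(deg[v] for v in e)
        if rule == "top_bottom":
            obs.append((ds[-1], ds[0]))
        elif rule == "top_2":
            obs.append((ds[-1], ds[-2]))
        elif rule == "uniform":
            obs.extend(itertools.combinations(ds, 2))
        else:
            raise ValueError(rule)
    if len(obs) < 2:
        return float("nan")
    xs = [a for a, b in obs] + [b for a, b in obs]
    ys = [b for a, b in obs] + [a for a, b in obs]
    return _pearson(xs, ys)


def _adjacency(nodes, edges) -> dict:
    adj = {v: set() for v in nodes}
    for e in edges:
        for u, v in itertools.combinations(list(e), 2):
            adj[u].add(v)
            adj[v].add(u)
    return adj


def brute_betweenness(nodes, edges) -> dict:
    """All-pairs BFS shortest-path counting on the co-membership graph.

    BC(n) = sum over unordered pairs (u, v), u != n != v, of
    sigma_uv(n) / sigma_uv, using sigma_uv(n) = sigma_un * sigma_nv when n
    lies on a shortest u-v path.
    """
    adj = _adjacency(nodes, edges)
    dist: dict = {}
    sigma: dict = {}
    for s in nodes:
        d = {s: 0}
        sg = {s: 1}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in d:
                    d[w] = d[u] + 1
                    sg[w] = 0
                    q.append(w)
                if d[w] == d[u] + 1:
                    sg[w] += sg[u]
        dist[s] = d
        sigma[s] = sg
    bc = {v: 0.0 for v in nodes}
    node_list = list(nodes)
    for i, u in enumerate(node_list):
        for v in node_list[i + 1 :]:
            if v not in dist[u]:
                continue
            duv = dist[u][v]
            for n in node_list:
                if n == u or n == v or n not in dist[u] or n not in dist[v]:
                    continue
                if dist[u][n] + dist[n][v] == duv:
                    bc[n] += sigma[u][n] * sigma[v][n] / sigma[u][v]
    return bc


def brute_best_label_overlap(ref_labels: list[int], other_labels: list[int]) -> float:
    """Max agreement over all injections of other-labels onto reference labels.

    Exhaustive search; feasible for <= 5 labels per side.
    """
    ref_ids = sorted(set(ref_labels))
    oth_ids = sorted(set(other_labels))
    n = len(ref_labels)
    best = 0
    # pad the smaller side with dummy ids so permutations cover injections
    size = max(len(ref_ids), len(oth_ids))
    padded_ref = ref_ids + [f"dummy{i}" for i in range(size - len(ref_ids))]
    for perm in itertools.permutations(padded_ref, len(oth_ids)):
        mapping = dict(zip(oth_ids, perm))
        agree = sum(1 for r, o in zip(ref_labels, other_labels) if mapping[o] == r)
        best = max(best, agree)
    return best / n


def random_hypergraph(rng, n_max=8, m_max=8, size_max=5, allow_dupes=True):
    """A small random hypergraph as (nodes, edges) plain structures."""
    n = rng.integers(2, n_max + 1)
    m = rng.integers(1, m_max + 1)
    nodes = list(range(n))
    edges = []
    for _ in range(m):
        s = int(rng.integers(1 if allow_dupes else 2, min(size_max, n) + 1))
        members = rng.choice(n, size=s, replace=False)
        edges.append(frozenset(int(x) for x in members))
    if not allow_dupes:
        seen = set()
        uniq = []
        for e in edges:
            if e not in seen:
                seen.add(e)
                uniq.append(e)
        edges = uniq
    return nodes, edges
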