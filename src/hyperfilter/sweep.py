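"""Sweep driver: every filter type over a k-range, metrics into a tidy table.

This reproduces the case-study workflow: preprocess a dataset, apply each of
the four size filters for each filtering parameter k, compute the requested
global and nodal measures on every filtering, and collect the results as
long-format records (one row per filter_type, k, metric, scope).

Undefined values — a uniform filtering at an absent size has no edges, so
effective information is simply not defined there — are kept as explicit NaN
rows, serialized as the literal token "NA", never silently dropped.
Community labels of every filtering are aligned to the reference labeling of
the full hypergraph via Hungarian matching so that label indices are
comparable across filter types and k.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .filtering import FILTER_OPS, SizeFilter, size_filter, sweep_k_range
from .global_measures import (
    dynamical_assortativity,
    effective_information,
    pearson_degree_assortativity,
)
from .hypergraph import Hypergraph
from .nodal_measures import (
    UNASSIGNED,
    CommunityLabeling,
    betweenness_centrality,
    match_labels,
    spectral_communities,
)

logger = logging.getLogger(__name__)

GLOBAL_METRICS = ("ei", "ei_norm", "rho_dyn", "assort_tb", "assort_t2", "assort_unif")
NODAL_METRICS = ("betweenness", "community")
ALL_METRICS = GLOBAL_METRICS + NODAL_METRICS

NA_TOKEN = "NA"


def _global_value(H: Hypergraph, metric: str) -> float:
    if metric == "ei":
        return effective_information(H).value
    if metric == "ei_norm":
        return effective_information(H, normalized=True).value
    if metric == "rho_dyn":
        return dynamical_assortativity(H).value
    rule = {"assort_tb": "top_bottom", "assort_t2": "top_2", "assort_unif": "uniform"}[
        metric
    ]
    return pearson_degree_assortativity(H, rule=rule).value


def sweep(
    H: Hypergraph,
    filter_types: Sequence[str] = FILTER_OPS,
    k_range: Iterable[int] | None = None,
    metrics: Sequence[str] = ("ei_norm", "rho_dyn"),
    communities: int = 2,
    seed: int = 0,
    normalized_bc: bool = False,
) -> pd.DataFrame:
    """Metric table over ``filter_types`` x ``k_range``.

    Columns: filter_type, k, metric, scope ("global" or "node:<label>"),
    value, seed, c.  ``k_range`` defaults to 2..max edge size.  Community
    labels are matched to the full hypergraph's labeling before being
    recorded.

    Raises
    ------
    ValueError
        On an unknown metric or filter name (listing the valid ones).
    """
    if not metrics:
        raise ValueError("metrics must be non-empty")
    for m in metrics:
        if m not in ALL_METRICS:
            raise ValueError(f"unknown metric {m!r}; valid metrics: {ALL_METRICS}")
    for ft in filter_types:
        if ft not in FILTER_OPS:
            raise ValueError(f"unknown filter type {ft!r}; valid: {FILTER_OPS}")
    ks = list(sweep_k_range(H) if k_range is None else k_range)
    reference: CommunityLabeling | None = None
    if "community" in metrics:
        reference = spectral_communities(H, c=communities, seed=seed)
    records: list[dict] = []
    for ft in filter_types:
        for k in ks:
            Hk = size_filter(H, SizeFilter(ft, k))
            if Hk.num_edges == 0:
                logger.info("filtering %s%d has no edges", ft, k)
            for m in metrics:
                common = dict(filter_type=ft, k=k, metric=m, seed=seed, c=communities)
                if m in GLOBAL_METRICS:
                    value = (
                        _global_value(Hk, m) if Hk.num_edges else float("nan")
                    )
                    records.append(dict(common, scope="global", value=value))
                elif m == "betweenness":
                    bc = betweenness_centrality(Hk, normalized=normalized_bc)
                    for v in H.nodes:
                        records.append(
                            dict(common, scope=f"node:{v}", value=bc[v])
                        )
                else:  # community
                    if Hk.num_edges == 0 or len(
                        set().union(*Hk.edges)
                    ) < communities:
                        labels = {v: UNASSIGNED for v in H.nodes}
                    else:
                        raw = spectral_communities(Hk, c=communities, seed=seed)
                        matched, _ = match_labels(reference, raw)
                        labels = matched.as_dict()
                    for v in H.nodes:
                        records.append(
                            dict(common, scope=f"node:{v}", value=float(labels[v]))
                        )
    return pd.DataFrame.from_records(
        records, columns=["filter_type", "k", "metric", "scope", "value", "seed", "c"]
    )


def write_metric_table(df: pd.DataFrame, path: str) -> None:
    """CSV with undefined values as the literal token NA."""
    df.to_csv(path, index=False, na_rep=NA_TOKEN)
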