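"""Reading and writing hypergraphs.

Two plain-text formats are supported:

* ``edgelist`` — UTF-8 text, one hyperedge per line, delimiter-separated node
  labels (default comma); lines starting with ``#`` are comments.  The format
  cannot represent isolated nodes.
* ``json`` — an object with ``"nodes"`` (list of labels) and ``"edges"``
  (list of lists of labels), plus optional ``"name"`` metadata.  This mirrors
  the JSON dialect used by public higher-order dataset collections, so
  datasets such as email-enron load unmodified.  Dialect variants that key
  edges by id (``{"edges": {"0": [..], ...}}``) or wrap members under
  ``"members"`` keys are accepted on read.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Any

from .hypergraph import Hypergraph

logger = logging.getLogger(__name__)

FORMATS = ("edgelist", "json")


class HypergraphParseError(ValueError):
    """Raised when an input file cannot be parsed as a hypergraph."""


def _infer_format(path: str) -> str:
    return "json" if os.path.splitext(path)[1].lower() == ".json" else "edgelist"


def load_hypergraph(
    path: str, format: str | None = None, delimiter: str = ","
) -> Hypergraph:
    """Load a hypergraph from ``path``.

    Node order is first-appearance order for edgelists and declared order for
    JSON.  Duplicate edges are preserved as read.

    Raises
    ------
    HypergraphParseError
        On malformed content (naming the offending line or key) or an empty
        file.
    """
    if format is None:
        format = _infer_format(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "edgelist":
        return _load_edgelist(path, delimiter)
    return _load_json(path)


def _load_edgelist(path: str, delimiter: str) -> Hypergraph:
    edges: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            members = [tok.strip() for tok in line.split(delimiter)]
            if any(tok == "" for tok in members):
                raise HypergraphParseError(
                    f"{path}:{lineno}: empty node label in line {line!r}"
                )
            edges.append(members)
    if not edges:
        raise HypergraphParseError(f"{path}: no hyperedges found (empty file?)")
    return Hypergraph(nodes=(), edges=edges)


def _edge_members(value: Any, key: str, path: str) -> list[Any]:
    if isinstance(value, dict) and "members" in value:
        value = value["members"]
    if not isinstance(value, list) or not value:
        raise HypergraphParseError(
            f"{path}: edge {key!r} is not a non-empty list of node labels"
        )
    return value


def _load_json(path: str) -> Hypergraph:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise HypergraphParseError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise HypergraphParseError(f"{path}: top-level JSON value must be an object")
    if "edges" not in doc:
        raise HypergraphParseError(f"{path}: missing required key 'edges'")
    raw_edges = doc["edges"]
    if isinstance(raw_edges, dict):
        items = list(raw_edges.items())
    elif isinstance(raw_edges, list):
        items = list(enumerate(raw_edges))  # type: ignore[arg-type]
    else:
        raise HypergraphParseError(f"{path}: 'edges' must be a list or an object")
    edges = [_edge_members(v, str(k), path) for k, v in items]
    nodes = doc.get("nodes", [])
    if isinstance(nodes, dict):  # node-keyed dialect: {"nodes": {"a": {...}}}
        nodes = list(nodes)
    if not isinstance(nodes, list):
        raise HypergraphParseError(f"{path}: 'nodes' must be a list")
    if not edges and not nodes:
        raise HypergraphParseError(f"{path}: hypergraph is empty")
    return Hypergraph(nodes=nodes, edges=edges, name=doc.get("name"))


def save_hypergraph(
    H: Hypergraph, path: str, format: str | None = None, delimiter: str = ","
) -> None:
    """Write ``H`` to ``path``.

    Round-trip guarantee: ``load(save(H))`` reproduces the node set and edge
    multiset (for edgelists, modulo isolated nodes, which the format cannot
    carry — a warning is logged when any would be lost).
    """
    if format is None:
        format = _infer_format(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format == "json":
        doc: dict[str, Any] = {
            "nodes": list(H.nodes),
            "edges": [sorted(e, key=str) for e in H.edges],
        }
        if H.name:
            doc["name"] = H.name
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
        return
    isolated = H.isolated_nodes()
    if isolated:
        logger.warning(
            "edgelist format cannot carry %d isolated node(s); they will be lost",
            len(isolated),
        )
    with open(path, "w", encoding="utf-8") as fh:
        for e in H.edges:
            fh.write(delimiter.join(str(v) for v in sorted(e, key=str)))
            fh.write("\n")
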