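"""File formats: GraphML / TSV network output and structured reports."""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import networkx as nx

from .builder import HierarchicalNetwork

__all__ = ["write_network", "read_network", "emit_report", "render_value"]


def _stringify(net: HierarchicalNetwork) -> nx.Graph:
    g = nx.Graph()
    rrns = set(net.rrns) if net.rrns else set()
    for n, data in net.graph.nodes(data=True):
        g.add_node(str(n), birth_generation=int(data.get("birth", 0)),
                   is_rrn=n in rrns)
    for u, v in net.graph.edges():
        g.add_edge(str(u), str(v))
    return g


def write_network(net: HierarchicalNetwork, path: str | Path,
                  fmt: str = "graphml") -> None:
    """Write a built network as GraphML (with ``birth_generation`` and
    ``is_rrn`` node attributes) or as a 2-column TSV edge list."""
    path = Path(path)
    g = _stringify(net)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt in ("edgelist", "tsv", "edgelist-tsv"):
        with path.open("w", encoding="utf-8") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
                fh.write(f"{u}\t{v}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path) -> HierarchicalNetwork:
    """Read back a GraphML network written by :func:`write_network`.

    Node ids come back as strings; birth generations and RRN markers are
    restored from attributes.
    """
    g = nx.read_graphml(Path(path))
    graph = nx.Graph()
    rrns = []
    for n, data in g.nodes(data=True):
        birth = int(data.get("birth_generation", 0))
        graph.add_node(n, birth=birth)
        if data.get("is_rrn"):
            rrns.append(n)
    graph.add_edges_from(g.edges())
    t = max((d["birth"] for _, d in graph.nodes(data=True)), default=0)
    return HierarchicalNetwork(graph, t, tuple(rrns) if len(rrns) == 2 else None,
                               {"source": str(path)})


def render_value(v):
    """JSON-friendly rendering; exact fractions become "p/q" plus decimal."""
    if isinstance(v, Fraction):
        return {"fraction": f"{v.numerator}/{v.denominator}", "value": float(v)}
    if isinstance(v, float) and (v != v or v in (float("inf"), float("-inf"))):
        return str(v)
    if isinstance(v, dict):
        return {str(k): render_value(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [render_value(x) for x in v]
    if hasattr(v, "tolist"):
        return v.tolist()
    return v


def emit_report(report: dict, path: str | Path) -> None:
    """Write a flat key-value report document as JSON."""
    doc = {k: render_value(v) for k, v in report.items()}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")
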