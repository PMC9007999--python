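"""Serialization: graphs to/from GraphML, DOT, JSON and arc CSV; tables to CSV."""

from __future__ import annotations

import json
import re
from pathlib import Path

import networkx as nx
import pandas as pd

from .feature_table import FeatureTable
from .graphs import Graph

__all__ = [
    "GRAPH_FORMATS",
    "load_feature_table",
    "export_graph",
    "load_graph",
    "graph_to_networkx",
    "graph_from_networkx",
]

GRAPH_FORMATS = ("graphml", "dot", "json", "csv-arcs")


def load_feature_table(path) -> FeatureTable:
    return FeatureTable.from_csv(path)


def graph_to_networkx(graph: Graph) -> nx.DiGraph:
    """Directed view; undirected edges carry ``directed="false"`` attributes."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for a, b in graph.sorted_arcs():
        g.add_edge(a, b, directed="true")
    for a, b in graph.sorted_undirected():
        g.add_edge(a, b, directed="false")
    return g


def graph_from_networkx(g: nx.DiGraph) -> Graph:
    out = Graph(sorted(g.nodes))
    for a, b, attrs in g.edges(data=True):
        if attrs.get("directed", "true") == "false":
            out.add_undirected(a, b)
        else:
            out.add_arc(a, b)
    return out


def _to_dot(graph: Graph) -> str:
    lines = ["digraph G {"]
    for n in graph.nodes:
        lines.append(f'  "{n}";')
    for a, b in graph.sorted_arcs():
        lines.append(f'  "{a}" -> "{b}";')
    for a, b in graph.sorted_undirected():
        lines.append(f'  "{a}" -> "{b}" [dir=none];')
    lines.append("}")
    return "\n".join(lines) + "\n"

_DOT_EDGE = re.compile(r'^\s*"([^"]+)"\s*->\s*"([^"]+)"\s*(\[dir=none\])?\s*;')
_DOT_NODE = re.compile(r'^\s*"([^"]+)"\s*;')


def _from_dot(text: str) -> Graph:
    nodes, arcs, und = [], [], []
    for line in text.splitlines():
        m = _DOT_EDGE.match(line)
        if m:
            a, b, undirected = m.groups()
            nodes.extend((a, b))
            (und if undirected else arcs).append((a, b))
            continue
        m = _DOT_NODE.match(line)
        if m:
            nodes.append(m.group(1))
    return Graph(dict.fromkeys(nodes), arcs, und)


def export_graph(graph: Graph, path, fmt: str | None = None) -> Path:
    """Write a graph to ``path``; format inferred from the suffix if omitted."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "graphml":
        nx.write_graphml(graph_to_networkx(graph), path)
    elif fmt == "dot":
        path.write_text(_to_dot(graph))
    elif fmt == "json":
        doc = {
            "nodes": list(graph.nodes),
            "arcs": graph.sorted_arcs(),
            "undirected": graph.sorted_undirected(),
        }
        path.write_text(json.dumps(doc, indent=2))
    elif fmt == "csv-arcs":
        rows = [
            {"parent": a, "child": b, "directed": True} for a, b in graph.sorted_arcs()
        ] + [
            {"parent": a, "child": b, "directed": False}
            for a, b in graph.sorted_undirected()
        ]
        pd.DataFrame(rows, columns=["parent", "child", "directed"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown graph format {fmt!r}; supported: {GRAPH_FORMATS}")
    return path


def load_graph(path, fmt: str | None = None) -> Graph:
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "graphml":
        return graph_from_networkx(nx.read_graphml(path))
    if fmt == "dot":
        return _from_dot(path.read_text())
    if fmt == "json":
        doc = json.loads(path.read_text())
        return Graph(
            doc["nodes"],
            [tuple(a) for a in doc["arcs"]],
            [tuple(e) for e in doc.get("undirected", [])],
        )
    if fmt == "csv-arcs":
        df = pd.read_csv(path)
        nodes = sorted(set(df["parent"]) | set(df["child"]))
        arcs = [
            (r["parent"], r["child"]) for _, r in df.iterrows() if r.get("directed", True)
        ]
        und = [
            (r["parent"], r["child"])
            for _, r in df.iterrows()
            if not r.get("directed", True)
        ]
        return Graph(nodes, arcs, und)
    raise ValueError(f"unknown graph format {fmt!r}; supported: {GRAPH_FORMATS}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    mapping = {"graphml": "graphml", "dot": "dot", "gv": "dot", "json": "json", "csv": "csv-arcs"}
    if suffix not in mapping:
        raise ValueError(
            f"cannot infer graph format from {path.name!r}; supported: {GRAPH_FORMATS}"
        )
    return mapping[suffix]
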