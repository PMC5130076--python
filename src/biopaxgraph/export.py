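"""Graph export: GraphML, DOT and a 3-column TSV edge list.

GraphML carries the full node (displayName, className, cellularLocation)
and edge (interactionType, sign, bidirectional) annotation; DOT is meant
for quick Graphviz rendering; the TSV edge list (source, target,
interactionType) is the minimal interchange form.
"""

from __future__ import annotations

import os

import networkx as nx

from .build import PathwayGraph

__all__ = ["to_graphml", "to_dot", "to_tsv", "write_graph"]


def to_graphml(graph: PathwayGraph, path: str | os.PathLike) -> None:
    g = graph.to_networkx()
    # GraphML has no graph-level string attr conventions nx respects on
    # read; booleans serialize natively.
    nx.write_graphml(g, str(path), named_key_ids=True)


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def to_dot(graph: PathwayGraph, path: str | os.PathLike) -> None:
    lines = [f'digraph "{_dot_escape(graph.pathway_id)}" {{']
    for node in graph.nodes.values():
        label = _dot_escape(node.display_name or node.local_id)
        lines.append(f'  "{_dot_escape(node.local_id)}" [label="{label}"];')
    for e in graph.edges:
        attrs = [f'label="{_dot_escape(e.interaction_type)}"']
        if e.bidirectional:
            attrs.append("dir=both")
        if e.sign == "inhibition":
            attrs.append("arrowhead=tee")
        lines.append(
            f'  "{_dot_escape(e.source)}" -> "{_dot_escape(e.target)}" '
            f'[{", ".join(attrs)}];'
        )
    lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def to_tsv(graph: PathwayGraph, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tinteractionType\n")
        for e in graph.edges:
            fh.write(f"{e.source}\t{e.target}\t{e.interaction_type}\n")


_WRITERS = {"graphml": to_graphml, "dot": to_dot, "tsv": to_tsv}


def write_graph(graph: PathwayGraph, path: str | os.PathLike,
                fmt: str) -> None:
    try:
        writer = _WRITERS[fmt]
    except KeyError:
        raise ValueError(
            f"unknown format {fmt!r}; expected one of {sorted(_WRITERS)}"
        ) from None
    writer(graph, path)
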