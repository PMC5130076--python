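"""Comparison machinery for regulatory vs full pathway graphs.

Incompletely annotated pathways fall apart into several weakly-connected
components when rebuilt as graphs; these helpers quantify that, diff the
two builders' outputs per pathway, and aggregate the diffs over a corpus
the way database-wide node/edge tallies are usually reported (per category,
with "how often is the full graph strictly/2x larger" fractions).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .build import PathwayGraph

__all__ = [
    "ComparisonRecord",
    "weak_components",
    "largest_component",
    "compare_graphs",
    "corpus_summary",
    "write_summary_tsv",
    "SUMMARY_COLUMNS",
]


@dataclass(frozen=True)
class ComparisonRecord:
    """Node/edge/component counts of one pathway under both semantics.

    ``shared_nodes + full_only_nodes == nodes_full`` always holds because
    the regulatory node set is a subset of the full node set.
    """

    pathway_id: str
    category: str
    nodes_regulatory: int
    edges_regulatory: int
    nodes_full: int
    edges_full: int
    shared_nodes: int
    full_only_nodes: int
    components_regulatory: int
    components_full: int


def weak_components(graph: PathwayGraph) -> list[set[str]]:
    """Partition the nodes under direction-blind reachability.

    Components are ordered largest first, ties broken by smallest
    lexicographic member ID.  An empty graph has an empty partition.
    """
    g = graph.to_networkx()
    comps = [set(c) for c in nx.weakly_connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def largest_component(graph: PathwayGraph) -> PathwayGraph:
    """Node-induced subgraph on the largest weak component.

    Equal-size components are resolved deterministically in favour of the
    one whose smallest member localID sorts first.  Idempotent; empty in,
    empty out.
    """
    comps = weak_components(graph)
    if not comps:
        return PathwayGraph(pathway_id=graph.pathway_id, mode=graph.mode)
    keep = comps[0]
    return PathwayGraph(
        pathway_id=graph.pathway_id,
        mode=graph.mode,
        nodes={k: v for k, v in graph.nodes.items() if k in keep},
        edges=[
            e for e in graph.edges if e.source in keep and e.target in keep
        ],
        warnings=list(graph.warnings),
    )


def compare_graphs(
    regulatory: PathwayGraph, full: PathwayGraph, category: str = ""
) -> ComparisonRecord:
    """Diff the two builders' outputs for one pathway.

    Bidirectional edges count once.  Raises ``ValueError`` when the graphs
    do not describe the same pathway or have the wrong modes.
    """
    if regulatory.pathway_id != full.pathway_id:
        raise ValueError(
            "graphs describe different pathways: "
            f"{regulatory.pathway_id!r} vs {full.pathway_id!r}"
        )
    if regulatory.mode != "regulatory" or full.mode != "full":
        raise ValueError(
            f"expected (regulatory, full) modes, got "
            f"({regulatory.mode!r}, {full.mode!r})"
        )
    shared = regulatory.node_ids & full.node_ids
    return ComparisonRecord(
        pathway_id=full.pathway_id,
        category=category,
        nodes_regulatory=len(regulatory.nodes),
        edges_regulatory=len(regulatory.edges),
        nodes_full=len(full.nodes),
        edges_full=len(full.edges),
        shared_nodes=len(shared),
        full_only_nodes=len(full.node_ids - regulatory.node_ids),
        components_regulatory=len(weak_components(regulatory)),
        components_full=len(weak_components(full)),
    )


SUMMARY_COLUMNS = [
    "Category",
    "P2RG Nodes",
    "P2RG Edges",
    "P2G Nodes",
    "P2G Edges",
    "Frac more nodes (P2G)",
    "Frac >=2x nodes",
    "Frac >=2x edges",
    "Frac disconnected (P2RG)",
    "Frac disconnected (P2G)",
]


def corpus_summary(records: list[ComparisonRecord]) -> pd.DataFrame:
    """Aggregate per-pathway comparison records per category.

    Sums node/edge counts and reports, per category, the fraction of
    pathways whose full graph has strictly more nodes, at least twice the
    nodes, at least twice the edges, and the fraction that are disconnected
    (more than one weak component) under each semantics.  Empty input
    yields an empty table.
    """
    if not records:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    df = pd.DataFrame(
        [
        {
            "Category": r.category,
            "nodes_reg": r.nodes_regulatory,
            "edges_reg": r.edges_regulatory,
            "nodes_full": r.nodes_full,
            "edges_full": r.edges_full,
            "more_nodes": r.nodes_full > r.nodes_regulatory,
            "nodes_2x": r.nodes_full >= 2 * r.nodes_regulatory,
            "edges_2x": r.edges_full >= 2 * r.edges_regulatory,
            "disc_reg": r.components_regulatory > 1,
            "disc_full": r.components_full > 1,
        }
        for r in records
        ]
    )
    grouped = df.groupby("Category", sort=True).agg(
        nodes_reg=("nodes_reg", "sum"),
        edges_reg=("edges_reg", "sum"),
        nodes_full=("nodes_full", "sum"),
        edges_full=("edges_full", "sum"),
        more_nodes=("more_nodes", "mean"),
        nodes_2x=("nodes_2x", "mean"),
        edges_2x=("edges_2x", "mean"),
        disc_reg=("disc_reg", "mean"),
        disc_full=("disc_full", "mean"),
    )
    grouped = grouped.reset_index()
    grouped.columns = SUMMARY_COLUMNS
    return grouped


def write_summary_tsv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False)
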