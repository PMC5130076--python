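"""Round-trip a fixture through RDF/XML and export its graph.

Writes a random pathway as a BioPAX .owl file, re-reads it, builds the
full graph restricted to its largest weak component, and exports it as
GraphML, DOT and a TSV edge list.
"""

import tempfile
from pathlib import Path

from biopaxgraph import (
    FixtureSpec,
    pathway_to_graph,
    random_pathway_fixture,
    read_biopax,
    write_biopax,
    write_graph,
)

out = Path(tempfile.mkdtemp(prefix="biopaxgraph_"))

doc = random_pathway_fixture(FixtureSpec(seed=42))
owl = out / "random42.owl"
write_biopax(doc, owl)

reloaded = read_biopax(owl)
print(f"round trip intact: {doc.structurally_equal(reloaded)} "
      f"({len(reloaded)} instances)")

graph = pathway_to_graph(reloaded, "Pathway1", only_largest_component=True)
print(f"largest component: {len(graph.nodes)} nodes, "
      f"{len(graph.edges)} edges")

for fmt in ("graphml", "dot", "tsv"):
    path = out / f"graph.{fmt}"
    write_graph(graph, path, fmt)
    print(f"wrote {fmt}: {path} ({path.stat().st_size} bytes)")

# The TSV holds one (source, target, interactionType) row per edge; the
# GraphML additionally carries display names, entity classes, compartments,
# signs and bidirectionality for use in Cytoscape or igraph.
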