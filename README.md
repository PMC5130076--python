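# biopaxgraph

Build directed graphs from BioPAX Level 3 pathway data, under two
semantics, and quantify what each recovers.

## The problem

Pathway databases such as Reactome distribute their content in BioPAX
(Biological Pathway Exchange), an OWL vocabulary over the RDF data model.
A BioPAX pathway is not a graph: it is a set of typed interaction records —
conversions with `left`/`right` participants, controls with a `controller`
and a `controlled` process, template reactions, unordered molecular
interactions — referencing physical entities (proteins, complexes, small
molecules, DNA, RNA).  Turning a pathway into a graph of its physical
entities is the first step of almost any network analysis, and the choice
of which interactions to honour changes the result substantially.

`biopaxgraph` implements both standard choices:

* **`pathway_to_regulatory_graph` (P2RG)** uses only the Control family
  (Control, Catalysis, Modulation, TemplateReactionRegulation).  Each edge
  runs from a controller entity to a participant of the controlled process
  and carries a sign — *activation* or *inhibition* — from `controlType`.
  The result is the regulatory skeleton of the pathway.

* **`pathway_to_graph` (P2G)** uses every interaction, adding the events
  regulation-only graphs miss: translocations, complex assemblies and
  dissociations, cleavages, template-directed synthesis, and unordered
  bindings (as bidirectional edges).  Because its interaction set is a
  superset, its node set always contains the regulatory node set.  It can
  optionally be restricted to the largest weakly-connected component.

When several interactions document a connection between the same two
entities, only the **first** connection (in document order) becomes an
edge; the dedup key is the unordered entity pair.  The comparison module
computes weak components, per-pathway node/edge diffs and corpus-style
category summaries; the fixture module generates valid BioPAX Level 3
documents — a curated apoptotic DNA-fragmentation pathway and seeded
random pathways — so everything is testable without database downloads.

## Worked example

```bash
python examples/worked_example.py
```

```
regulatory graph: 7 nodes, 6 edges, 2 weak components
full graph:       23 nodes, 26 edges, 1 weak components
entities visible only to the full builder: 16
translocation: Active CASP3 (Cytosol) -> Active CASP3 (Nucleoplasm) via Transport
```

The fixture is the apoptotic DNA-fragmentation pathway (caspase-3
activation of the DFF/CAD nuclease and chromatin cleavage) with the 23
physical entities Reactome annotates for it.  Only 7 of them take part in
regulation, so the regulatory builder recovers 7 nodes — in two
disconnected fragments, the caspase arm and the nuclease arm.  The full
builder recovers all 23 entities in one connected graph; the extra 16
include cytosolic active caspase-3, whose move into the nucleus is a
Transport, not a regulation, and hence invisible to the regulatory
builder.

The same from the shell:

```bash
biopaxgraph fixture canonical --out canonical.owl
biopaxgraph compare canonical.owl
biopaxgraph graph canonical.owl --pathway Pathway140342 \
    --mode full --format graphml --out full.graphml
```

Other examples: `examples/random_corpus_summary.py` (category summary over
50 random pathways), `examples/export_formats.py` (RDF/XML round trip and
GraphML/DOT/TSV export).

## Scope

RDF/XML is the only supported serialization (the dialect Reactome
distributes); BioPAX Level 2 files are rejected.  No OWL reasoning, no
SPARQL, no stoichiometry-aware hypergraphs.  See `docs/methods.md` for the
edge semantics table, design decisions and limitations.
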