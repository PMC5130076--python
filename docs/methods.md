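# Methods

## Data model

A BioPAX Level 3 file is parsed into a `BiopaxDocument`: an ordered table
of `BiopaxInstance` records (localID, class name, property map).  Property
values are either resource references (pointing at another localID) or
literals, and value lists keep file order.  Order is semantic throughout:
the first-connection deduplication rule below is defined in terms of it,
which is why the reader is built on lxml over the striped RDF/XML dialect
Reactome emits rather than on a triple store (a triple store normalizes
statement order away).  Consequences of that choice: only RDF/XML is
supported, typed nodes must be top-level elements bearing `rdf:about` or
`rdf:ID`, and nested anonymous resources are not interpreted.

The class hierarchy is a fixed tree rooted at `Entity`, covering the
Interaction family (Conversion → BiochemicalReaction/Degradation,
ComplexAssembly, Transport, TransportWithBiochemicalReaction; Control →
Catalysis, Modulation, TemplateReactionRegulation; TemplateReaction;
MolecularInteraction; GeneticInteraction), the PhysicalEntity family
(Protein, Complex, SmallMolecule, Dna, Rna, DnaRegion, RnaRegion),
Pathway/PathwayStep, and utility classes (vocabularies, xrefs,
stoichiometry), which are parsed generically but carry no graph
semantics.  Subclass queries are reflexive; unknown class names are
errors.

Property names are normalized by stripping the namespace prefix and
lowercasing the first letter, because exporters disagree on
`pathwayComponent` vs `PathwayComponent`.  Dangling references are kept
and surfaced by `BiopaxDocument.dangling_references()` rather than
repaired or dropped: incomplete annotation is precisely what makes rebuilt
pathways fall apart into disconnected components, and the tool must not
mask it.

A pathway's interactions are collected both from direct
`pathwayComponent` references and via `pathwayOrder` → PathwayStep →
`stepProcess` (Reactome uses both), deduplicated, in document order.
Sub-pathways are expanded only on request (`recurse_sub_pathways=True`);
the default treats each pathway independently so shared sub-pathways are
not double-counted in corpus statistics.

## Edge semantics

Nodes are physical entities only; entities touching no interaction never
appear as isolated nodes, so node counts equal edge-endpoint counts.  Per
interaction class:

| class family | edges |
| --- | --- |
| Conversion | every `left` → every `right`; bidirectional iff `conversionDirection` = REVERSIBLE (default direction is left-to-right) |
| Control | every `controller` entity → every participant of the `controlled` process (lefts and rights of a conversion; template and products of a template reaction; participants of a molecular interaction); if the controlled process is itself a Control, the targets are its controller entities, keeping nodes strictly physical entities |
| TemplateReaction | `template` → every `product` |
| MolecularInteraction, GeneticInteraction | one bidirectional edge per unordered participant pair |

Edge signs: `controlType` prefixes ACTIVATION*/INHIBITION* map to
activation/inhibition.  An absent controlType means activation for
Catalysis — catalysis is inherently activating in the BioPAX definition —
and unspecified for other controls.  Non-control edges are always
unspecified.  Self-connections are never emitted; bidirectional edges are
stored once, flagged, and count once in every total.

**First-connection rule.**  Interactions are processed in document order,
each generating edges in the fixed per-class order above.  The first edge
for an unordered entity pair is kept; every later edge on the same pair —
including one running the opposite way — is dropped.  Treating the pair as
unordered is a deliberate choice: the alternative (directed-pair keys)
would let two opposed conversions produce a 2-cycle, and node/edge totals
would stop being comparable across builders.

The regulatory builder applies this machinery to the pathway's
Control-family interactions only; the full builder to all of them.  Since
the regulatory interaction set is a subset, regulatory nodes and unordered
edge pairs are provably contained in the full graph's — a property test
asserts this over seeded random fixtures.  A pathway without controls
yields an empty regulatory graph; that is data, not an error (whole
database categories are unregulated).

## Metrics

Components are weak (direction-blind); a pathway is *disconnected* when it
has more than one.  `largest_component` induces the subgraph on the
largest weak component, with equal sizes resolved toward the component
whose smallest member localID sorts first — an arbitrary but deterministic
tie-break.  `compare_graphs` produces per-pathway count records
(`shared + full_only = full` holds by the subset property) and
`corpus_summary` aggregates them per category: summed counts plus the
fractions of pathways with strictly more / at-least-double nodes or edges
under full semantics, and the disconnected fraction under each semantics.
Category labels are caller-supplied metadata, not inferred from content.

## Fixtures

**Canonical fixture.**  The apoptotic DNA-fragmentation pathway.  Its 23
physical entities (localIDs, display names, compartments) are annotated
database facts, copied verbatim.  The interaction list is a
*reconstruction* — the event wiring is not published as a table — built
from the pathway's biology: DFF assembly and importin-mediated nuclear
import, caspase-3 translocation, caspase cleavage of DFFA, CAD nuclease
assembly and chromatin binding, DNA cleavage and its stimulation by
HMGB1/HMGB2.  It is committed as documented data in
`fixtures.CANONICAL_INTERACTIONS` (one comment per interaction) and as a
golden `.owl` file; the generator reproduces the golden file exactly.
The wiring is constrained so that the 3 Control-family interactions touch
exactly the 7 regulated entities and the 11 remaining interactions connect
all 23 entities into one weak component — giving 7 regulatory nodes / 6
signed edges (two weak components) and 23 full nodes / 26 edges (one
component).  Two simplifications are documented in the source: importin
recycling is folded into the nuclear dissociation step, and the cleaved
DFF complex dissociates in a single reaction with five products.

**Random fixtures.**  `random_pathway_fixture(FixtureSpec(...))` emits
Reactome-shaped documents: one Pathway listing all interactions through
PathwaySteps, conversions with 1–3 left and 1–3 right participants,
controls aimed at random conversions with controlType drawn from
{ACTIVATION, INHIBITION, absent}, molecular interactions over 2–4
participants, and location vocabulary defaulting to
{Cytosol, Nucleoplasm}.  Defaults (12 entities, 6 conversions, 3 controls,
1 undirected interaction) give small pathways of the size the worked
example has, which is representative of a single curated pathway rather
than of a whole database.  With probability 0.1 a conversion deliberately
re-documents an entity pair an earlier conversion already connected
(sometimes flipped), so the first-connection rule is exercised routinely;
15% of conversions are REVERSIBLE.  Output is byte-deterministic per
seed.  What the generator does *not* emulate: Reactome's xref/provenance
annotation depth, entity references, sub-pathway nesting, and the heavy
right-tail of pathway sizes — so passing property tests demonstrate the
algorithms' contracts, not database-scale statistics.

## Numerical and degenerate-input choices

* Empty pathway, pathway without controls, empty graph into
  `largest_component` or `weak_components`: all yield empty results, never
  errors.
* A Control whose `controlled` cannot be resolved produces zero edges plus
  a warning record on the graph; dangling participant references are
  likewise skipped and recorded.
* Participants outside the PhysicalEntity family (e.g. a controller that
  is a Pathway) are ignored, preserving the nodes-are-entities invariant.
* Duplicate localIDs and empty localIDs are rejected at document assembly.
* Determinism: two runs over the same file produce identical node sets and
  edge orders; fixture generation is deterministic per seed.

## Limitations

No OWL reasoning or ontology validation; BioPAX Level 2 is rejected
rather than translated.  Stoichiometry is ignored (graphs, not
hypergraphs).  Complexes are nodes; they are not expanded into member
molecules.  The Turtle/N-Triples serializations are unsupported.  Corpus
summaries at real-database scale require the database export itself; the
metrics are exercised here on fixtures.
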