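"""Convert one BioPAX pathway into a directed graph of physical entities.

Two semantics are offered:

* :func:`pathway_to_regulatory_graph` (the field's P2RG) uses only the
  Control family — Control, Catalysis, Modulation and
  TemplateReactionRegulation — so every edge is a regulation event signed
  activation or inhibition.  Entities that merely react, translocate or
  assemble without regulating anything are invisible to it.

* :func:`pathway_to_graph` (P2G) uses every interaction of the pathway, so
  translocations, complex assemblies, cleavages and unordered bindings also
  contribute edges.  Its node set always contains the regulatory graph's
  node set, and it can optionally be restricted to the largest
  weakly-connected component.

Edge semantics per interaction class
------------------------------------
Conversion family
    one edge from every ``left`` participant to every ``right`` participant;
    bidirectional when ``conversionDirection`` is REVERSIBLE (the default
    direction is left-to-right).
Control family
    one edge from every ``controller`` entity to every participant of the
    ``controlled`` interaction (its lefts and rights for a conversion,
    template and products for a template reaction, participants for a
    molecular interaction).  When the controlled process is itself a
    Control, edges target the inner controller entities instead, keeping
    nodes strictly physical entities.  Sign comes from ``controlType``
    (ACTIVATION*/INHIBITION* prefixes); an absent controlType means
    activation for Catalysis (catalysis is inherently activating) and
    unspecified otherwise.
TemplateReaction
    one edge from the ``template`` to every ``product``.
MolecularInteraction / GeneticInteraction
    one bidirectional edge per unordered pair of ``participant`` entities.

When several interactions document a connection between the same two
entities, only the first connection encountered (document order of
interactions, then the per-interaction order above) becomes an edge; later
ones — including ones running the opposite way — are dropped.  The
deduplication key is the unordered entity pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .model import (
    BiopaxDocument,
    BiopaxInstance,
    is_subclass_of,
    pathway_interactions,
    subclass_closure,
)

__all__ = [
    "GraphNode",
    "GraphEdge",
    "PathwayGraph",
    "interaction_edges",
    "pathway_to_regulatory_graph",
    "pathway_to_graph",
    "ACTIVATION",
    "INHIBITION",
    "UNSPECIFIED",
]

ACTIVATION = "activation"
INHIBITION = "inhibition"
UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class GraphNode:
    """A physical entity appearing as an endpoint of at least one edge."""

    local_id: str
    display_name: str
    class_name: str
    cellular_location: str = ""


@dataclass(frozen=True)
class GraphEdge:
    """One directed connection between two physical entities.

    ``bidirectional`` edges (reversible conversions, unordered molecular
    interactions) are stored once with the flag set, never as two records,
    and count once toward edge totals.
    """

    source: str
    target: str
    interaction_type: str
    sign: str = UNSPECIFIED
    bidirectional: bool = False
    generating_interaction: str = ""

    def unordered_pair(self) -> frozenset[str]:
        return frozenset((self.source, self.target))


@dataclass
class PathwayGraph:
    """Directed graph of one pathway under regulatory or full semantics."""

    pathway_id: str
    mode: str  # "regulatory" | "full"
    nodes: dict[str, GraphNode] = field(default_factory=dict)
    edges: list[GraphEdge] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def node_ids(self) -> set[str]:
        return set(self.nodes)

    def edge_pairs(self) -> set[frozenset[str]]:
        """The unordered endpoint pairs of all edges."""
        return {e.unordered_pair() for e in self.edges}

    def to_networkx(self) -> "nx.DiGraph":
        """Render as a networkx DiGraph.  Bidirectional edges become a
        single arc with ``bidirectional=True`` — direction-blind analyses
        (weak components) are unaffected and edge totals stay well defined."""
        g = nx.DiGraph(pathway_id=self.pathway_id, mode=self.mode)
        for node in self.nodes.values():
            g.add_node(
                node.local_id,
                displayName=node.display_name,
                className=node.class_name,
                cellularLocation=node.cellular_location,
            )
        for e in self.edges:
            g.add_edge(
                e.source,
                e.target,
                interactionType=e.interaction_type,
                sign=e.sign,
                bidirectional=e.bidirectional,
                generatingInteraction=e.generating_interaction,
            )
        return g


_ENTITY_CLASSES = subclass_closure("PhysicalEntity")
_CONTROL_CLASSES = subclass_closure("Control")
_CONVERSION_CLASSES = subclass_closure("Conversion")
_INTERACTION_CLASSES = subclass_closure("Interaction")


def _entity_refs(
    doc: BiopaxDocument, inst: BiopaxInstance, prop: str, warnings: list[str]
) -> list[str]:
    """Resolve a participant property to physical-entity localIDs, keeping
    order and dropping duplicates, dangling targets and non-entities."""
    out: list[str] = []
    for ref in inst.refs(prop):
        target = doc.get(ref)
        if target is None:
            warnings.append(
                f"{inst.local_id}.{prop}: dangling reference {ref!r}"
            )
            continue
        if target.class_name not in _ENTITY_CLASSES:
            continue
        if ref not in out:
            out.append(ref)
    return out


def _control_sign(inst: BiopaxInstance) -> str:
    control_type = inst.first_literal("controlType").upper()
    if control_type.startswith("ACTIVATION"):
        return ACTIVATION
    if control_type.startswith("INHIBITION"):
        return INHIBITION
    if is_subclass_of(inst.class_name, "Catalysis"):
        return ACTIVATION
    return UNSPECIFIED


def _control_targets(
    doc: BiopaxDocument, control: BiopaxInstance, warnings: list[str]
) -> list[str]:
    """Physical entities a control's edges point at: the participants of the
    controlled process, or the inner controller when controls are chained."""
    targets: list[str] = []
    for cid in control.refs("controlled"):
        inner = doc.get(cid)
        if inner is None:
            warnings.append(
                f"{control.local_id}.controlled: dangling reference {cid!r}"
            )
            continue
        cls = inner.class_name
        if cls in _CONTROL_CLASSES:
            targets += _entity_refs(doc, inner, "controller", warnings)
        elif cls in _CONVERSION_CLASSES:
            targets += _entity_refs(doc, inner, "left", warnings)
            targets += _entity_refs(doc, inner, "right", warnings)
        elif cls == "TemplateReaction":
            targets += _entity_refs(doc, inner, "template", warnings)
            targets += _entity_refs(doc, inner, "product", warnings)
        elif cls in _INTERACTION_CLASSES:
            targets += _entity_refs(doc, inner, "participant", warnings)
        else:
            warnings.append(
                f"{control.local_id}: controlled {cid!r} is a {cls}, "
                "not an interaction; skipped"
            )
    seen: list[str] = []
    for t in targets:
        if t not in seen:
            seen.append(t)
    return seen


def interaction_edges(
    doc: BiopaxDocument, interaction_id: str
) -> tuple[list[GraphEdge], list[str]]:
    """Edges generated by one interaction, in the fixed per-class order.

    Returns ``(edges, warnings)``.  Self-connections are never emitted.
    Raises ``ValueError`` when ``interaction_id`` is not in the Interaction
    family.
    """
    inst = doc.get(interaction_id)
    if inst is None:
        raise KeyError(f"unknown localID: {interaction_id!r}")
    cls = inst.class_name
    if cls not in _INTERACTION_CLASSES:
        raise ValueError(f"{interaction_id!r} is a {cls}, not an Interaction")

    warnings: list[str] = []
    edges: list[GraphEdge] = []

    def emit(src: str, dst: str, sign: str, bidir: bool) -> None:
        if src == dst:
            return
        edges.append(
            GraphEdge(
                source=src,
                target=dst,
                interaction_type=cls,
                sign=sign,
                bidirectional=bidir,
                generating_interaction=interaction_id,
            )
        )

    if cls in _CONVERSION_CLASSES:
        lefts = _entity_refs(doc, inst, "left", warnings)
        rights = _entity_refs(doc, inst, "right", warnings)
        reversible = (
            inst.first_literal("conversionDirection").upper() == "REVERSIBLE"
        )
        for left in lefts:
            for right in rights:
                emit(left, right, UNSPECIFIED, reversible)
    elif cls in _CONTROL_CLASSES:
        controllers = _entity_refs(doc, inst, "controller", warnings)
        targets = _control_targets(doc, inst, warnings)
        if not targets:
            warnings.append(
                f"{inst.local_id}: no resolvable controlled participants; "
                "zero edges"
            )
        sign = _control_sign(inst)
        for controller in controllers:
            for target in targets:
                emit(controller, target, sign, False)
    elif cls == "TemplateReaction":
        templates = _entity_refs(doc, inst, "template", warnings)
        products = _entity_refs(doc, inst, "product", warnings)
        for template in templates:
            for product in products:
                emit(template, product, UNSPECIFIED, False)
    else:  # MolecularInteraction, GeneticInteraction, bare Interaction
        participants = _entity_refs(doc, inst, "participant", warnings)
        for i, a in enumerate(participants):
            for b in participants[i + 1:]:
                emit(a, b, UNSPECIFIED, True)
    return edges, warnings


def _location_term(doc: BiopaxDocument, inst: BiopaxInstance) -> str:
    """Cellular location of an entity: either a literal on the entity or a
    reference into a CellularLocationVocabulary carrying a ``term``."""
    lits = inst.literals("cellularLocation")
    if lits:
        return lits[0]
    for ref in inst.refs("cellularLocation"):
        vocab = doc.get(ref)
        if vocab is not None:
            term = vocab.first_literal("term")
            if term:
                return term
    return ""


def _node(doc: BiopaxDocument, local_id: str) -> GraphNode:
    inst = doc[local_id]
    return GraphNode(
        local_id=local_id,
        display_name=inst.first_literal("displayName")
        or inst.first_literal("name", local_id),
        class_name=inst.class_name,
        cellular_location=_location_term(doc, inst),
    )


def _assemble(
    doc: BiopaxDocument,
    pathway_id: str,
    interaction_ids: list[str],
    mode: str,
) -> PathwayGraph:
    """Run the per-interaction semantics in document order and apply the
    first-connection rule: one edge per unordered entity pair, earliest
    generating interaction wins."""
    graph = PathwayGraph(pathway_id=pathway_id, mode=mode)
    seen_pairs: set[frozenset[str]] = set()
    for iid in interaction_ids:
        edges, warnings = interaction_edges(doc, iid)
        graph.warnings.extend(warnings)
        for edge in edges:
            pair = edge.unordered_pair()
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            graph.edges.append(edge)
            for endpoint in (edge.source, edge.target):
                if endpoint not in graph.nodes:
                    graph.nodes[endpoint] = _node(doc, endpoint)
    return graph


def pathway_to_regulatory_graph(
    doc: BiopaxDocument, pathway_id: str
) -> PathwayGraph:
    """Build the regulatory (P2RG) graph of one pathway.

    Only Control-family interactions contribute, so the result is the
    activation/inhibition skeleton of the pathway.  A pathway with no
    controls yields an empty graph — a real situation, not an error: whole
    Reactome categories (e.g. scavenger-receptor ligand uptake) contain no
    regulation at all.
    """
    ids = [
        iid
        for iid in pathway_interactions(doc, pathway_id)
        if doc[iid].class_name in _CONTROL_CLASSES
    ]
    return _assemble(doc, pathway_id, ids, mode="regulatory")


def pathway_to_graph(
    doc: BiopaxDocument,
    pathway_id: str,
    only_largest_component: bool = False,
) -> PathwayGraph:
    """Build the full (P2G) graph of one pathway from every interaction.

    ``only_largest_component`` restricts the result to the largest
    weakly-connected component, discarding fragments that arise from
    incompletely annotated pathways.
    """
    ids = pathway_interactions(doc, pathway_id)
    graph = _assemble(doc, pathway_id, ids, mode="full")
    if only_largest_component:
        from .metrics import largest_component

        graph = largest_component(graph)
    return graph
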