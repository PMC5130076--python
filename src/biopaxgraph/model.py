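"""In-memory data model for BioPAX Level 3 content.

BioPAX organises pathway knowledge into a class hierarchy rooted at
``Entity``: physical entities (proteins, complexes, small molecules, ...),
interactions between them (conversions, controls, template reactions, ...),
and the ``Pathway``/``PathwayStep`` containers that group interactions into
pathways.  This module holds the parsed instances of one BioPAX document and
the hierarchy/reference queries the graph builders rely on.

Instance order and property-value order always follow the source file: the
graph builders resolve duplicate connections between the same pair of
entities by keeping the first one encountered, so order is semantic here,
not cosmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Union

__all__ = [
    "ResourceRef",
    "Literal",
    "BiopaxInstance",
    "BiopaxDocument",
    "CLASS_HIERARCHY",
    "UnknownClassError",
    "is_subclass_of",
    "subclass_closure",
    "instances_of_class",
    "referenced_ids",
    "pathway_interactions",
    "normalize_property",
]


@dataclass(frozen=True)
class ResourceRef:
    """A property value pointing at another instance by localID."""

    id: str


@dataclass(frozen=True)
class Literal:
    """A plain string property value (display names, control types, ...)."""

    value: str


PropertyValue = Union[ResourceRef, Literal]


def normalize_property(name: str) -> str:
    """Canonical predicate spelling: namespace prefix stripped, first letter
    lowercased.  Reactome exporters disagree on the capitalisation of e.g.
    ``pathwayComponent`` / ``PathwayComponent``; comparing case-insensitively
    on the first letter absorbs that dialect difference.
    """
    if ":" in name:
        name = name.rsplit(":", 1)[1]
    if not name:
        return name
    return name[0].lower() + name[1:]


@dataclass
class BiopaxInstance:
    """One RDF resource of a BioPAX class.

    ``properties`` maps normalized predicate names to ordered value lists;
    each value is a :class:`ResourceRef` (points at another localID) or a
    :class:`Literal`.
    """

    local_id: str
    class_name: str
    properties: dict[str, list[PropertyValue]] = field(default_factory=dict)

    def add(self, prop: str, value: PropertyValue) -> None:
        self.properties.setdefault(normalize_property(prop), []).append(value)

    def values(self, prop: str) -> list[PropertyValue]:
        return self.properties.get(normalize_property(prop), [])

    def refs(self, prop: str) -> list[str]:
        """LocalIDs of all resource-reference values of ``prop``, in order."""
        return [v.id for v in self.values(prop) if isinstance(v, ResourceRef)]

    def literals(self, prop: str) -> list[str]:
        return [v.value for v in self.values(prop) if isinstance(v, Literal)]

    def first_literal(self, prop: str, default: str = "") -> str:
        lits = self.literals(prop)
        return lits[0] if lits else default

    def all_refs(self) -> Iterator[tuple[str, str]]:
        """Yield (property, target localID) for every resource reference."""
        for prop, vals in self.properties.items():
            for v in vals:
                if isinstance(v, ResourceRef):
                    yield prop, v.id


class UnknownClassError(KeyError):
    """A class name absent from the BioPAX Level 3 hierarchy table."""

    def __init__(self, class_name: str):
        super().__init__(class_name)
        self.class_name = class_name

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"unknown BioPAX class: {self.class_name!r}"


# child -> parent, rooted at Entity.  Covers the classes Reactome Level 3
# exports actually instantiate; utility classes carry no graph semantics but
# are parsed and classified like everything else.
CLASS_HIERARCHY: dict[str, str | None] = {
    "Entity": None,
    "Pathway": "Entity",
    "PathwayStep": "Entity",
    "BiochemicalPathwayStep": "PathwayStep",
    # interactions
    "Interaction": "Entity",
    "Conversion": "Interaction",
    "BiochemicalReaction": "Conversion",
    "Degradation": "BiochemicalReaction",
    "ComplexAssembly": "Conversion",
    "Transport": "Conversion",
    "TransportWithBiochemicalReaction": "Conversion",
    "Control": "Interaction",
    "Catalysis": "Control",
    "Modulation": "Control",
    "TemplateReactionRegulation": "Control",
    "TemplateReaction": "Interaction",
    "MolecularInteraction": "Interaction",
    "GeneticInteraction": "Interaction",
    # physical entities
    "PhysicalEntity": "Entity",
    "Protein": "PhysicalEntity",
    "Complex": "PhysicalEntity",
    "SmallMolecule": "PhysicalEntity",
    "Dna": "PhysicalEntity",
    "Rna": "PhysicalEntity",
    "DnaRegion": "PhysicalEntity",
    "RnaRegion": "PhysicalEntity",
    # utility classes (generic parse, no graph semantics)
    "UtilityClass": "Entity",
    "Stoichiometry": "UtilityClass",
    "CellularLocationVocabulary": "UtilityClass",
    "Provenance": "UtilityClass",
    "Evidence": "UtilityClass",
    "Xref": "UtilityClass",
    "UnificationXref": "Xref",
    "RelationshipXref": "Xref",
    "PublicationXref": "Xref",
    "EntityReference": "UtilityClass",
    "ProteinReference": "EntityReference",
    "SmallMoleculeReference": "EntityReference",
    "DnaReference": "EntityReference",
    "RnaReference": "EntityReference",
    "BioSource": "UtilityClass",
    "SequenceModificationVocabulary": "UtilityClass",
    "SequenceSite": "UtilityClass",
    "ModificationFeature": "UtilityClass",
    "FragmentFeature": "UtilityClass",
}


def is_subclass_of(child: str, ancestor: str) -> bool:
    """True iff ``ancestor`` lies on the parent chain of ``child``.

    Reflexive: every class is a subclass of itself.  Raises
    :class:`UnknownClassError` for names outside the hierarchy table.
    """
    for name in (child, ancestor):
        if name not in CLASS_HIERARCHY:
            raise UnknownClassError(name)
    cur: str | None = child
    while cur is not None:
        if cur == ancestor:
            return True
        cur = CLASS_HIERARCHY[cur]
    return False


def subclass_closure(ancestor: str) -> frozenset[str]:
    """All class names that are ``ancestor`` or one of its descendants."""
    if ancestor not in CLASS_HIERARCHY:
        raise UnknownClassError(ancestor)
    return frozenset(
        c for c in CLASS_HIERARCHY if is_subclass_of(c, ancestor)
    )


@dataclass
class BiopaxDocument:
    """Parsed instance table of one BioPAX file.

    ``instances`` is keyed by localID and iterates in file order.
    ``level`` is always 3; Level 2 input is rejected at read time.
    """

    instances: dict[str, BiopaxInstance] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    level: int = 3

    def add(self, instance: BiopaxInstance) -> None:
        if not instance.local_id:
            raise ValueError("instance localID must be non-empty")
        if instance.local_id in self.instances:
            raise ValueError(f"duplicate localID: {instance.local_id!r}")
        self.instances[instance.local_id] = instance

    def __iter__(self) -> Iterator[BiopaxInstance]:
        return iter(self.instances.values())

    def __len__(self) -> int:
        return len(self.instances)

    def __contains__(self, local_id: str) -> bool:
        return local_id in self.instances

    def __getitem__(self, local_id: str) -> BiopaxInstance:
        return self.instances[local_id]

    def get(self, local_id: str) -> BiopaxInstance | None:
        return self.instances.get(local_id)

    def order_index(self, local_id: str) -> int:
        """Position of an instance in file order (used for dedup ordering)."""
        for i, key in enumerate(self.instances):
            if key == local_id:
                return i
        raise KeyError(local_id)

    def dangling_references(self) -> list[tuple[str, str, str]]:
        """All (source localID, property, target localID) triples whose
        target names no instance in this document.  Dangling references are
        reported, never repaired: missing content is exactly what produces
        disconnected pathway graphs downstream, and silently dropping it
        would mask that."""
        out = []
        for inst in self:
            for prop, target in inst.all_refs():
                if target not in self.instances:
                    out.append((inst.local_id, prop, target))
        return out

    def structurally_equal(self, other: "BiopaxDocument") -> bool:
        """Equality on the model content: same instances in the same order,
        same classes, same property maps (order-sensitive).  Namespace
        bookkeeping is ignored."""
        if list(self.instances) != list(other.instances):
            return False
        for a, b in zip(self, other):
            if a.class_name != b.class_name or a.properties != b.properties:
                return False
        return True


def instances_of_class(
    doc: BiopaxDocument, class_name: str, include_subclasses: bool = True
) -> list[str]:
    """LocalIDs of all instances of ``class_name``, in document order.

    With ``include_subclasses`` membership is decided by the hierarchy
    (e.g. a ``Catalysis`` instance is returned for ``class_name="Control"``).
    Instances whose class is absent from the hierarchy table never match a
    family query, but asking for an unknown class is an error.
    """
    if class_name not in CLASS_HIERARCHY:
        raise UnknownClassError(class_name)
    if include_subclasses:
        members = subclass_closure(class_name)
        return [i.local_id for i in doc if i.class_name in members]
    return [i.local_id for i in doc if i.class_name == class_name]


def referenced_ids(
    doc: BiopaxDocument, start_id: str, transitive: bool = True
) -> set[str]:
    """All localIDs reachable from ``start_id`` through resource-reference
    property values.  ``transitive=False`` scans only the start instance's
    direct references; ``True`` computes the closure.  Dangling references
    are skipped (they resolve to nothing).  The start is excluded from the
    result.
    """
    if start_id not in doc:
        raise KeyError(f"unknown localID: {start_id!r}")
    seen: set[str] = set()
    frontier = [start_id]
    while frontier:
        cur = frontier.pop()
        inst = doc.get(cur)
        if inst is None:  # dangling: skip
            continue
        for _, target in inst.all_refs():
            if target != start_id and target not in seen:
                seen.add(target)
                if transitive:
                    frontier.append(target)
    return seen


_INTERACTION_CLASSES = None  # filled lazily; avoids import-order surprises


def _interaction_classes() -> frozenset[str]:
    global _INTERACTION_CLASSES
    if _INTERACTION_CLASSES is None:
        _INTERACTION_CLASSES = subclass_closure("Interaction")
    return _INTERACTION_CLASSES


def pathway_interactions(
    doc: BiopaxDocument, pathway_id: str, recurse_sub_pathways: bool = False
) -> list[str]:
    """All Interaction-subclass instances belonging to a pathway.

    Interactions are gathered both from direct ``pathwayComponent``
    references and via ``pathwayOrder`` → PathwayStep → ``stepProcess``
    (Reactome uses both routes), deduplicated, and returned in document
    order.  Sub-pathways listed as components are expanded only when
    ``recurse_sub_pathways`` is set; the default treats every pathway as an
    independent unit so shared sub-pathways are not double-counted.
    """
    root = doc.get(pathway_id)
    if root is None:
        raise KeyError(f"unknown localID: {pathway_id!r}")
    if not is_subclass_of(root.class_name, "Pathway"):
        raise ValueError(
            f"{pathway_id!r} is a {root.class_name}, not a Pathway"
        )

    interactions: set[str] = set()
    visited_pathways: set[str] = set()
    step_classes = subclass_closure("PathwayStep")
    pathway_classes = subclass_closure("Pathway")

    def visit(pid: str) -> None:
        if pid in visited_pathways:
            return
        visited_pathways.add(pid)
        pw = doc.get(pid)
        if pw is None:
            return
        candidates = list(pw.refs("pathwayComponent"))
        for step_id in pw.refs("pathwayOrder"):
            step = doc.get(step_id)
            if step is not None and step.class_name in step_classes:
                candidates.extend(step.refs("stepProcess"))
        for cid in candidates:
            target = doc.get(cid)
            if target is None:
                continue
            if target.class_name in _interaction_classes():
                interactions.add(cid)
            elif target.class_name in pathway_classes and recurse_sub_pathways:
                visit(cid)

    visit(pathway_id)
    order = {local_id: i for i, local_id in enumerate(doc.instances)}
    return sorted(interactions, key=order.__getitem__)
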