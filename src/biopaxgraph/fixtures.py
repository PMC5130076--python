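"""Synthetic BioPAX Level 3 documents for testing and demonstration.

Two generators:

* :func:`dna_fragmentation_fixture` — the apoptotic DNA-fragmentation
  pathway (DFF/CAD activation and chromatin cleavage) with the 23 physical
  entities Reactome v51 annotates for it, identifiers, display names and
  compartments verbatim.  The entity table is database-derived; the
  interaction wiring is a documented reconstruction (see below) because the
  event list itself is not tabulated anywhere — it is rebuilt from the
  pathway's biology so that the regulatory builder sees exactly the 7
  regulated entities and the full builder all 23 in one connected graph.

* :func:`random_pathway_fixture` — seeded random pathways mimicking
  Reactome's instance structure (Pathway → PathwaySteps → interactions →
  entities, location vocabulary), for property-based testing.  Byte-
  deterministic under a fixed spec.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .model import BiopaxDocument, BiopaxInstance, Literal, ResourceRef

__all__ = [
    "FixtureSpec",
    "dna_fragmentation_fixture",
    "random_pathway_fixture",
    "canonical_fixture_path",
    "CANONICAL_PATHWAY_ID",
    "CANONICAL_ENTITIES",
    "CANONICAL_INTERACTIONS",
]


def canonical_fixture_path() -> Path:
    """Location of the committed golden copy of the canonical fixture
    (identical to the output of :func:`dna_fragmentation_fixture`)."""
    return Path(__file__).parent / "data" / "apoptosis_dna_fragmentation.owl"

CANONICAL_PATHWAY_ID = "Pathway140342"

# (localID, class, displayName, cellular location) — the 23 physical
# entities of 'Apoptosis induced DNA fragmentation' as annotated in
# Reactome v51, copied verbatim.
CANONICAL_ENTITIES: list[tuple[str, str, str, str]] = [
    ("Protein8776", "Protein", "DFFB", "Cytosol"),
    ("Protein8777", "Protein", "DFFA", "Cytosol"),
    ("Complex4232", "Complex", "DFFA : DFFB", "Cytosol"),
    ("Complex4233", "Complex", "Importin alpha : Importin beta", "Cytosol"),
    ("Complex4234", "Complex",
     "DFF : associated with Importin alpha : Importin beta", "Cytosol"),
    ("Complex4235", "Complex",
     "DFF : associated with Importin alpha : Importin beta", "Nucleoplasm"),
    ("Complex4169", "Complex", "Active CASP3", "Cytosol"),
    ("Complex4238", "Complex", "Active CASP3", "Nucleoplasm"),
    ("Complex4236", "Complex", "DFFA : DFFB", "Nucleoplasm"),
    ("Complex4239", "Complex", "Caspase cleaved DFFA", "Nucleoplasm"),
    ("Complex4240", "Complex", "Caspase cleaved DFFA : DFFB", "Nucleoplasm"),
    ("Protein8779", "Protein", "DFFB", "Nucleoplasm"),
    ("Protein8784", "Protein", "DFFA fragment", "Nucleoplasm"),
    ("Protein8785", "Protein", "DFFA fragment", "Nucleoplasm"),
    ("Protein8783", "Protein", "DFFA fragment", "Nucleoplasm"),
    ("Complex4241", "Complex", "DFFB homodimer", "Nucleoplasm"),
    ("PhysicalEntity567", "PhysicalEntity",
     "DFFB homodimer/homooligomer", "Nucleoplasm"),
    ("Complex2061", "Complex", "Histone H1 bound chromatin DNA",
     "Nucleoplasm"),
    ("Complex4242", "Complex", "DFFB associated with chromatin",
     "Nucleoplasm"),
    ("Protein8786", "Protein", "HMGB1/HMGB2", "Nucleoplasm"),
    ("PhysicalEntity109", "PhysicalEntity", "DNA", "Nucleoplasm"),
    ("Complex4243", "Complex", "HMGB1/HMGB2 – bound chromatin",
     "Nucleoplasm"),
    ("Complex4244", "Complex", "DFF cleaved DNA", "Nucleoplasm"),
]

# The interaction wiring of the pathway, reconstructed from its biology
# (synthetic: the event list is not published as a table; IDs are ours).
# Each entry: (localID, class, displayName, properties-dict).  Document
# order here is the order the graph builders iterate in, so it fixes which
# edge wins when two interactions connect the same entity pair.
#
# Regulatory skeleton (the 3 Control-family events touch exactly
# Complex4238, Complex4236, Complex4240, PhysicalEntity567, Complex4242,
# Complex4243, Complex4244):
#   Catalysis1: nuclear caspase-3 (4238) catalyses the DFFA cleavage
#   Catalysis2: the DFFB oligomer (567) catalyses chromatin DNA cleavage
#   Control1:   HMGB1/HMGB2-bound chromatin (4243) stimulates that cleavage
CANONICAL_INTERACTIONS: list[tuple[str, str, str, dict]] = [
    # DFFA and DFFB associate into the DFF heterodimer (cytosol)
    ("ComplexAssembly1", "ComplexAssembly", "DFFA binds DFFB",
     {"left": ["Protein8777", "Protein8776"], "right": ["Complex4232"]}),
    # DFF binds the importin alpha:beta carrier
    ("ComplexAssembly2", "ComplexAssembly", "DFF binds importins",
     {"left": ["Complex4232", "Complex4233"], "right": ["Complex4234"]}),
    # the DFF:importin cargo translocates into the nucleus
    ("Transport1", "Transport", "DFF:importin complex enters the nucleus",
     {"left": ["Complex4234"], "right": ["Complex4235"]}),
    # importins are released, leaving nuclear DFF; the carrier is recycled
    ("BiochemicalReaction1", "BiochemicalReaction",
     "Importins dissociate from nuclear DFF",
     {"left": ["Complex4235"], "right": ["Complex4236", "Complex4233"]}),
    # active caspase-3 translocates from cytosol to nucleoplasm
    # (4169 -> 4238: visible only to the full builder, since 4169
    # regulates nothing)
    ("Transport2", "Transport", "Active CASP3 enters the nucleus",
     {"left": ["Complex4169"], "right": ["Complex4238"]}),
    # caspase-3 cleaves DFFA within nuclear DFF (controlled by Catalysis1)
    ("BiochemicalReaction2", "BiochemicalReaction",
     "Caspase-3 cleaves DFFA within DFF",
     {"left": ["Complex4236"], "right": ["Complex4240"]}),
    # the cleaved complex breaks up into its individual components:
    # cleaved DFFA (4239), free nuclear DFFB and the three DFFA fragments
    ("BiochemicalReaction3", "BiochemicalReaction",
     "Caspase-cleaved DFF dissociates",
     {"left": ["Complex4240"],
      "right": ["Complex4239", "Protein8779", "Protein8783",
                "Protein8784", "Protein8785"]}),
    # released DFFB homodimerizes and oligomerizes into active CAD nuclease
    ("ComplexAssembly3", "ComplexAssembly",
     "DFFB forms homodimers/homooligomers",
     {"left": ["Protein8779"],
      "right": ["Complex4241", "PhysicalEntity567"]}),
    # the DFFB oligomer associates with histone-H1-bound chromatin
    ("ComplexAssembly4", "ComplexAssembly", "DFFB binds chromatin",
     {"left": ["PhysicalEntity567", "Complex2061"],
      "right": ["Complex4242"]}),
    # chromatin-bound DFFB cleaves the DNA (controlled by Catalysis2 and
    # Control1)
    ("BiochemicalReaction4", "BiochemicalReaction",
     "DFF cleaves chromatin DNA",
     {"left": ["Complex4242"], "right": ["Complex4244"]}),
    # HMGB1/HMGB2 bind (linker) DNA, giving HMGB-bound chromatin
    ("ComplexAssembly5", "ComplexAssembly", "HMGB1/HMGB2 bind DNA",
     {"left": ["Protein8786", "PhysicalEntity109"],
      "right": ["Complex4243"]}),
    # --- Control family ---
    ("Catalysis1", "Catalysis", "Caspase-3 catalyses DFFA cleavage",
     {"controller": ["Complex4238"],
      "controlled": ["BiochemicalReaction2"],
      "controlType": "ACTIVATION"}),
    ("Catalysis2", "Catalysis", "CAD nuclease activity",
     {"controller": ["PhysicalEntity567"],
      "controlled": ["BiochemicalReaction4"]}),
    ("Control1", "Control", "HMGB1/HMGB2 stimulate DNA cleavage",
     {"controller": ["Complex4243"],
      "controlled": ["BiochemicalReaction4"],
      "controlType": "ACTIVATION"}),
]

_LOCATION_IDS = {"Cytosol": "CellularLocationVocabulary1",
                 "Nucleoplasm": "CellularLocationVocabulary2"}

_REFERENCE_PROPS = {"left", "right", "controller", "controlled",
                    "template", "product", "participant",
                    "cellularLocation", "pathwayComponent",
                    "pathwayOrder", "stepProcess", "nextStep"}


def _make_instance(local_id: str, class_name: str,
                   display_name: str | None, props: dict) -> BiopaxInstance:
    inst = BiopaxInstance(local_id=local_id, class_name=class_name)
    if display_name is not None:
        inst.add("displayName", Literal(display_name))
    for prop, values in props.items():
        if isinstance(values, str):
            values = [values]
        for v in values:
            if prop in _REFERENCE_PROPS:
                inst.add(prop, ResourceRef(v))
            else:
                inst.add(prop, Literal(v))
    return inst


def dna_fragmentation_fixture() -> BiopaxDocument:
    """The apoptotic DNA-fragmentation pathway as a BioPAX document.

    23 physical entities (database-verbatim), 14 interactions (reconstructed
    wiring, 3 of them Control-family), one pathway listing every interaction
    through PathwaySteps — with one interaction additionally listed as a
    direct ``pathwayComponent`` to exercise the dedup of the two routes.
    """
    doc = BiopaxDocument()

    pathway = _make_instance(
        CANONICAL_PATHWAY_ID, "Pathway", "Apoptosis induced DNA fragmentation",
        {"pathwayComponent": ["BiochemicalReaction2"]},
    )
    step_ids = []
    for i, (iid, _, _, _) in enumerate(CANONICAL_INTERACTIONS, start=1):
        step_ids.append((f"PathwayStep{i}", iid))
    for sid, _ in step_ids:
        pathway.add("pathwayOrder", ResourceRef(sid))
    doc.add(pathway)
    for sid, iid in step_ids:
        doc.add(_make_instance(sid, "PathwayStep", None,
                               {"stepProcess": [iid]}))

    for iid, cls, name, props in CANONICAL_INTERACTIONS:
        doc.add(_make_instance(iid, cls, name, props))

    for eid, cls, name, location in CANONICAL_ENTITIES:
        doc.add(_make_instance(
            eid, cls, name, {"cellularLocation": [_LOCATION_IDS[location]]}
        ))

    for term, vid in sorted(_LOCATION_IDS.items(), key=lambda kv: kv[1]):
        doc.add(_make_instance(vid, "CellularLocationVocabulary", None,
                               {"term": term}))
    return doc


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one random pathway fixture.

    ``n_controls`` may not exceed ``n_conversions``: every control needs a
    conversion to regulate.  A fixed seed reproduces the document (and its
    serialization) byte for byte.
    """

    n_entities: int = 12
    n_conversions: int = 6
    n_controls: int = 3
    n_undirected: int = 1
    seed: int = 0
    location_vocabulary: tuple[str, ...] = ("Cytosol", "Nucleoplasm")

    def validate(self) -> None:
        if min(self.n_entities, self.n_conversions, self.n_controls,
               self.n_undirected) < 0:
            raise ValueError("fixture counts must be non-negative")
        if self.n_controls > self.n_conversions:
            raise ValueError(
                "n_controls must not exceed n_conversions "
                "(every control needs a controlled conversion)"
            )
        n_interactions = self.n_conversions + self.n_undirected
        if n_interactions > 0 and self.n_entities < 2:
            raise ValueError(
                "interactions require at least 2 entities"
            )


_ENTITY_POOL = ["Protein", "Complex", "SmallMolecule", "Dna", "Rna",
                "PhysicalEntity"]
_CONVERSION_POOL = ["BiochemicalReaction", "ComplexAssembly", "Transport",
                    "Degradation"]
_CONTROL_POOL = ["Catalysis", "Control", "Modulation"]

# Fraction of conversions that deliberately re-connect an entity pair an
# earlier conversion already connected, so the first-connection rule is
# routinely exercised by property tests.
_DUPLICATE_RATE = 0.1
_REVERSIBLE_RATE = 0.15


def random_pathway_fixture(spec: FixtureSpec) -> BiopaxDocument:
    """One random Reactome-shaped pathway document, deterministic per seed.

    Entities get random PhysicalEntity subclasses and locations from the
    spec's vocabulary; conversions draw 1–3 left and 1–3 right participants
    (disjoint); controls pick a random conversion to regulate with a
    controlType drawn from {ACTIVATION, INHIBITION, absent}; undirected
    interactions are MolecularInteractions over 2–4 participants.  A single
    Pathway lists all interactions through PathwaySteps.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    doc = BiopaxDocument()

    entity_ids = []
    entity_specs = []
    for i in range(spec.n_entities):
        cls = rng.choice(_ENTITY_POOL)
        eid = f"{cls}{i + 1}"
        entity_ids.append(eid)
        entity_specs.append(
            (eid, cls, f"Entity {i + 1}",
             rng.choice(spec.location_vocabulary))
        )

    def sample_disjoint(n_left: int, n_right: int) -> tuple[list, list]:
        picked = rng.sample(entity_ids, min(n_left + n_right,
                                            len(entity_ids)))
        return picked[:n_left], picked[n_left:n_left + n_right]

    interactions: list[tuple[str, str, str, dict]] = []
    conversion_ids: list[str] = []
    connected_pairs: list[tuple[str, str]] = []
    for i in range(spec.n_conversions):
        cls = rng.choice(_CONVERSION_POOL)
        iid = f"{cls}_c{i + 1}"
        if connected_pairs and rng.random() < _DUPLICATE_RATE:
            # re-document an existing connection, sometimes flipped
            a, b = rng.choice(connected_pairs)
            if rng.random() < 0.5:
                a, b = b, a
            lefts, rights = [a], [b]
        else:
            lefts, rights = sample_disjoint(rng.randint(1, 3),
                                            rng.randint(1, 3))
        if not rights:  # tiny entity pools can exhaust the sample
            lefts, rights = sample_disjoint(1, 1)
        props: dict = {"left": lefts, "right": rights}
        if rng.random() < _REVERSIBLE_RATE:
            props["conversionDirection"] = "REVERSIBLE"
        interactions.append((iid, cls, f"Conversion {i + 1}", props))
        conversion_ids.append(iid)
        connected_pairs.extend((l, r) for l in lefts for r in rights)

    for i in range(spec.n_controls):
        cls = rng.choice(_CONTROL_POOL)
        iid = f"{cls}_r{i + 1}"
        controllers = rng.sample(entity_ids, rng.randint(1, 2))
        props = {
            "controller": controllers,
            "controlled": [rng.choice(conversion_ids)],
        }
        control_type = rng.choice(["ACTIVATION", "INHIBITION", None])
        if control_type is not None:
            props["controlType"] = control_type
        interactions.append((iid, cls, f"Control {i + 1}", props))

    for i in range(spec.n_undirected):
        iid = f"MolecularInteraction_u{i + 1}"
        participants = rng.sample(
            entity_ids, min(rng.randint(2, 4), len(entity_ids))
        )
        interactions.append(
            (iid, "MolecularInteraction", f"Binding {i + 1}",
             {"participant": participants})
        )

    location_ids = {
        term: f"CellularLocationVocabulary{j + 1}"
        for j, term in enumerate(spec.location_vocabulary)
    }

    pathway = _make_instance(
        "Pathway1", "Pathway", f"Random pathway (seed {spec.seed})", {}
    )
    for i, (iid, _, _, _) in enumerate(interactions, start=1):
        pathway.add("pathwayOrder", ResourceRef(f"PathwayStep{i}"))
    doc.add(pathway)
    for i, (iid, _, _, _) in enumerate(interactions, start=1):
        doc.add(_make_instance(f"PathwayStep{i}", "PathwayStep", None,
                               {"stepProcess": [iid]}))
    for iid, cls, name, props in interactions:
        doc.add(_make_instance(iid, cls, name, props))
    for eid, cls, name, location in entity_specs:
        doc.add(_make_instance(
            eid, cls, name, {"cellularLocation": [location_ids[location]]}
        ))
    for term, vid in location_ids.items():
        doc.add(_make_instance(vid, "CellularLocationVocabulary", None,
                               {"term": term}))
    return doc
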