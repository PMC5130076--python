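"""Edge semantics per interaction class and the two graph builders."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biopaxgraph import (
    BiopaxDocument,
    BiopaxInstance,
    FixtureSpec,
    Literal,
    ResourceRef,
    interaction_edges,
    pathway_to_graph,
    pathway_to_regulatory_graph,
    random_pathway_fixture,
)
from biopaxgraph.build import ACTIVATION, INHIBITION, UNSPECIFIED


def make_doc(*instances):
    """Assemble a document from (id, class, {prop: [ids-or-literal]}) specs;
    string values for 'controlType', 'conversionDirection', 'displayName'
    and 'term' are literals, everything else a reference."""
    literal_props = {"controlType", "conversionDirection", "displayName",
                     "term"}
    doc = BiopaxDocument()
    for local_id, cls, props in instances:
        inst = BiopaxInstance(local_id, cls)
        for prop, values in props.items():
            if isinstance(values, str):
                values = [values]
            for v in values:
                if prop in literal_props:
                    inst.add(prop, Literal(v))
                else:
                    inst.add(prop, ResourceRef(v))
        doc.add(inst)
    return doc


def entities(*ids, cls="Protein"):
    return [(i, cls, {"displayName": i}) for i in ids]


class TestInteractionEdges:
    def test_conversion_left_to_right(self):
        doc = make_doc(
            ("R", "BiochemicalReaction", {"left": ["A", "B"],
                                          "right": ["C"]}),
            *entities("A", "B", "C"),
        )
        edges, _ = interaction_edges(doc, "R")
        assert [(e.source, e.target) for e in edges] == [("A", "C"),
                                                         ("B", "C")]
        assert all(e.sign == UNSPECIFIED and not e.bidirectional
                   for e in edges)
        assert all(e.interaction_type == "BiochemicalReaction"
                   for e in edges)

    def test_reversible_conversion_is_bidirectional(self):
        doc = make_doc(
            ("R", "BiochemicalReaction",
             {"left": ["A"], "right": ["B"],
              "conversionDirection": "REVERSIBLE"}),
            *entities("A", "B"),
        )
        edges, _ = interaction_edges(doc, "R")
        assert len(edges) == 1 and edges[0].bidirectional

    def test_transport_single_edge(self):
        # a translocation: the same molecule in two compartments
        doc = make_doc(
            ("T", "Transport", {"left": ["Complex4169"],
                                "right": ["Complex4238"]}),
            *entities("Complex4169", "Complex4238", cls="Complex"),
        )
        edges, _ = interaction_edges(doc, "T")
        assert [(e.source, e.target, e.interaction_type) for e in edges] == [
            ("Complex4169", "Complex4238", "Transport")
        ]

    @pytest.mark.parametrize(
        "control_type,cls,expected_sign",
        [
            ("ACTIVATION", "Control", ACTIVATION),
            ("ACTIVATION-ALLOSTERIC", "Modulation", ACTIVATION),
            ("INHIBITION", "Control", INHIBITION),
            ("INHIBITION-COMPETITIVE", "Catalysis", INHIBITION),
            (None, "Catalysis", ACTIVATION),  # catalysis activates by default
            (None, "Control", UNSPECIFIED),
            (None, "Modulation", UNSPECIFIED),
        ],
    )
    def test_control_sign(self, control_type, cls, expected_sign):
        props = {"controller": ["E"], "controlled": ["R"]}
        if control_type is not None:
            props["controlType"] = control_type
        doc = make_doc(
            (
                "R",
                "BiochemicalReaction",
                {"left": ["A"], "right": ["B"]},
            ),
            ("C", cls, props),
            *entities("A", "B", "E"),
        )
        edges, _ = interaction_edges(doc, "C")
        assert {(e.source, e.target) for e in edges} == {("E", "A"),
                                                         ("E", "B")}
        assert {e.sign for e in edges} == {expected_sign}

    def test_control_targets_left_and_right_of_controlled(self):
        doc = make_doc(
            ("R", "BiochemicalReaction",
             {"left": ["Complex4236"], "right": ["Complex4240"]}),
            ("C", "Catalysis", {"controller": ["Complex4238"],
                                "controlled": ["R"],
                                "controlType": "ACTIVATION"}),
            *entities("Complex4236", "Complex4240", "Complex4238",
                      cls="Complex"),
        )
        edges, _ = interaction_edges(doc, "C")
        assert [(e.source, e.target, e.sign) for e in edges] == [
            ("Complex4238", "Complex4236", ACTIVATION),
            ("Complex4238", "Complex4240", ACTIVATION),
        ]

    def test_chained_control_targets_inner_controller(self):
        doc = make_doc(
            ("R", "BiochemicalReaction", {"left": ["A"], "right": ["B"]}),
            ("Inner", "Catalysis", {"controller": ["E1"],
                                    "controlled": ["R"]}),
            ("Outer", "Modulation", {"controller": ["E2"],
                                     "controlled": ["Inner"],
                                     "controlType": "INHIBITION"}),
            *entities("A", "B", "E1", "E2"),
        )
        edges, _ = interaction_edges(doc, "Outer")
        assert [(e.source, e.target, e.sign) for e in edges] == [
            ("E2", "E1", INHIBITION)
        ]

    def test_control_without_resolvable_controlled_warns(self):
        doc = make_doc(
            ("C", "Control", {"controller": ["E"], "controlled": ["Ghost"]}),
            *entities("E"),
        )
        edges, warnings = interaction_edges(doc, "C")
        assert edges == []
        assert any("Ghost" in w for w in warnings)

    def test_template_reaction_template_to_products(self):
        doc = make_doc(
            ("T", "TemplateReaction", {"template": ["D"],
                                       "product": ["R1", "R2"]}),
            ("D", "Dna", {}),
            ("R1", "Rna", {}),
            ("R2", "Protein", {}),
        )
        edges, _ = interaction_edges(doc, "T")
        assert [(e.source, e.target) for e in edges] == [("D", "R1"),
                                                         ("D", "R2")]

    def test_molecular_interaction_all_pairs_bidirectional(self):
        doc = make_doc(
            ("M", "MolecularInteraction",
             {"participant": ["A", "B", "C"]}),
            *entities("A", "B", "C"),
        )
        edges, _ = interaction_edges(doc, "M")
        assert [(e.source, e.target) for e in edges] == [
            ("A", "B"), ("A", "C"), ("B", "C")
        ]
        assert all(e.bidirectional for e in edges)

    def test_molecular_interaction_single_participant_no_edges(self):
        doc = make_doc(
            ("M", "MolecularInteraction", {"participant": ["A"]}),
            *entities("A"),
        )
        edges, _ = interaction_edges(doc, "M")
        assert edges == []

    def test_self_conversion_emits_no_self_loop(self):
        doc = make_doc(
            ("R", "BiochemicalReaction", {"left": ["A"],
                                          "right": ["A", "B"]}),
            *entities("A", "B"),
        )
        edges, _ = interaction_edges(doc, "R")
        assert [(e.source, e.target) for e in edges] == [("A", "B")]

    def test_non_interaction_rejected(self, canonical_doc):
        with pytest.raises(ValueError):
            interaction_edges(canonical_doc, "Complex4238")
        with pytest.raises(KeyError):
            interaction_edges(canonical_doc, "NoSuchID")


def _pathway_doc(*interactions, extra_entities=()):
    """A single pathway wrapping the given interaction specs."""
    inter_ids = [i[0] for i in interactions]
    pw = ("P", "Pathway", {"pathwayComponent": inter_ids})
    ents = set(extra_entities)
    for _, _, props in interactions:
        for prop in ("left", "right", "controller", "participant",
                     "template", "product"):
            vals = props.get(prop, [])
            ents.update([vals] if isinstance(vals, str) else vals)
    ents -= set(inter_ids)
    return make_doc(pw, *interactions, *entities(*sorted(ents)))


class TestBuilders:
    def test_regulatory_canonical(self, regulatory_graph):
        assert regulatory_graph.mode == "regulatory"
        assert len(regulatory_graph.nodes) == 7
        assert {(e.source, e.target) for e in regulatory_graph.edges} == {
            ("Complex4238", "Complex4236"),
            ("Complex4238", "Complex4240"),
            ("PhysicalEntity567", "Complex4242"),
            ("PhysicalEntity567", "Complex4244"),
            ("Complex4243", "Complex4242"),
            ("Complex4243", "Complex4244"),
        }
        assert all(e.sign == ACTIVATION for e in regulatory_graph.edges)

    def test_full_canonical(self, full_graph, regulatory_graph):
        assert full_graph.mode == "full"
        assert len(full_graph.nodes) == 23
        assert len(full_graph.edges) == 26
        assert len(full_graph.node_ids - regulatory_graph.node_ids) == 16

    def test_full_canonical_largest_component_is_identity(
        self, canonical_doc, canonical_pathway_id, full_graph
    ):
        restricted = pathway_to_graph(
            canonical_doc, canonical_pathway_id, only_largest_component=True
        )
        assert restricted.node_ids == full_graph.node_ids
        assert [(e.source, e.target) for e in restricted.edges] == [
            (e.source, e.target) for e in full_graph.edges
        ]

    def test_node_annotations_from_canonical(self, full_graph):
        node = full_graph.nodes["Complex4169"]
        assert node.display_name == "Active CASP3"
        assert node.class_name == "Complex"
        assert node.cellular_location == "Cytosol"
        assert full_graph.nodes["Complex4238"].cellular_location == \
            "Nucleoplasm"

    def test_pathway_without_controls_gives_empty_regulatory_graph(self):
        doc = _pathway_doc(
            ("R1", "BiochemicalReaction", {"left": ["A"], "right": ["B"]}),
            ("T1", "Transport", {"left": ["B"], "right": ["C"]}),
        )
        reg = pathway_to_regulatory_graph(doc, "P")
        full = pathway_to_graph(doc, "P")
        assert (len(reg.nodes), len(reg.edges)) == (0, 0)
        assert len(full.nodes) == 3 and len(full.edges) == 2

    def test_first_connection_rule_keeps_earliest(self):
        doc = _pathway_doc(
            ("R1", "BiochemicalReaction", {"left": ["A"], "right": ["B"]}),
            ("R2", "Transport", {"left": ["A"], "right": ["B"]}),
            ("R3", "Transport", {"left": ["B"], "right": ["A"]}),  # opposed
        )
        full = pathway_to_graph(doc, "P")
        assert len(full.edges) == 1
        edge = full.edges[0]
        assert (edge.source, edge.target) == ("A", "B")
        assert edge.generating_interaction == "R1"
        assert edge.interaction_type == "BiochemicalReaction"

    def test_dedup_key_is_unordered_pair(self, full_graph):
        pairs = [e.unordered_pair() for e in full_graph.edges]
        assert len(pairs) == len(set(pairs))

    def test_entities_outside_interactions_are_not_nodes(self):
        doc = _pathway_doc(
            ("R1", "BiochemicalReaction", {"left": ["A"], "right": ["B"]}),
            extra_entities=("Lonely",),
        )
        full = pathway_to_graph(doc, "P")
        assert full.node_ids == {"A", "B"}

    def test_non_entity_participants_are_skipped(self):
        # a Control whose controller is a Pathway contributes nothing
        doc = make_doc(
            ("P", "Pathway", {"pathwayComponent": ["R", "C"]}),
            ("P2", "Pathway", {}),
            ("R", "BiochemicalReaction", {"left": ["A"], "right": ["B"]}),
            ("C", "Catalysis", {"controller": ["P2"], "controlled": ["R"]}),
            *entities("A", "B"),
        )
        full = pathway_to_graph(doc, "P")
        assert full.node_ids == {"A", "B"}
        assert len(full.edges) == 1

    def test_bidirectional_stored_once(self):
        doc = _pathway_doc(
            ("M", "MolecularInteraction", {"participant": ["A", "B"]}),
        )
        full = pathway_to_graph(doc, "P")
        assert len(full.edges) == 1 and full.edges[0].bidirectional


@settings(deadline=None, max_examples=60)
@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_regulatory_graph_is_subgraph_of_full(seed):
    """Nodes and unordered edge pairs of the regulatory builder are always
    contained in the full builder's output."""
    doc = random_pathway_fixture(FixtureSpec(seed=seed))
    reg = pathway_to_regulatory_graph(doc, "Pathway1")
    full = pathway_to_graph(doc, "Pathway1")
    assert reg.node_ids <= full.node_ids
    assert reg.edge_pairs() <= full.edge_pairs()


@settings(deadline=None, max_examples=40)
@given(seed=st.integers(min_value=0, max_value=2**31 - 1))
def test_builders_are_deterministic_and_self_loop_free(seed):
    doc = random_pathway_fixture(FixtureSpec(seed=seed))
    runs = [pathway_to_graph(doc, "Pathway1") for _ in range(2)]
    assert runs[0].node_ids == runs[1].node_ids
    assert [(e.source, e.target) for e in runs[0].edges] == [
        (e.source, e.target) for e in runs[1].edges
    ]
    for e in runs[0].edges:
        assert e.source != e.target
        assert e.source in runs[0].nodes and e.target in runs[0].nodes
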