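import pytest

from biopaxgraph import (
    dna_fragmentation_fixture,
    pathway_to_graph,
    pathway_to_regulatory_graph,
)
from biopaxgraph.fixtures import CANONICAL_PATHWAY_ID


@pytest.fixture(scope="session")
def canonical_doc():
    return dna_fragmentation_fixture()


@pytest.fixture(scope="session")
def canonical_pathway_id():
    return CANONICAL_PATHWAY_ID


@pytest.fixture(scope="session")
def regulatory_graph(canonical_doc):
    return pathway_to_regulatory_graph(canonical_doc, CANONICAL_PATHWAY_ID)


@pytest.fixture(scope="session")
def full_graph(canonical_doc):
    return pathway_to_graph(canonical_doc, CANONICAL_PATHWAY_ID)
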