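import pytest
from rdflib import Graph

from rdfqa import (
    ForgeSpec,
    OfflineTransport,
    assess_document,
    forge_resource,
)
from rdfqa.inventory import document_from_graph


def turtle_doc(text: str, identifier: str = "urn:rdfqa:test"):
    graph = Graph()
    graph.parse(data=text, format="turtle")
    return document_from_graph(graph, identifier=identifier)


@pytest.fixture
def registry_like_spec():
    """54 URIs, 6 non-resolvable, 10 literals, 47 triples — the shape of
    a small patient-registry metadata document."""
    return ForgeSpec(seed=1, n_uris=54, non_resolvable=6,
                     n_literals=10, n_triples=47)


@pytest.fixture
def registry_like(registry_like_spec):
    return forge_resource(registry_like_spec)


@pytest.fixture
def registry_assessment(registry_like):
    transport = OfflineTransport(registry_like.fixture_map, strict=True)
    return assess_document(registry_like.document, transport)
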