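"""DQV assessment reports and SPARQL quality queries.

Assessment results are serialized with the W3C Data Quality Vocabulary:
the assessed resource is a ``dcat:Resource`` linked via
``dqv:hasQualityMeasurement`` to one measurement node per metric; each
measurement carries ``dqv:isMeasurementOf`` (the metric URI),
``dqv:value`` (the lexical fraction, e.g. ``"6/54"``),
``prov:generatedAtTime``, and one ``dcterms:relation`` link per
erroneous URI.

Three bundled SPARQL queries interrogate a store of such reports:

1. which resources have more than 10% non-resolvable URIs;
2. which resources use undefined URIs, and which URIs;
3. which quality issues a given resource has, with metric definitions.
"""

from __future__ import annotations

import hashlib
from datetime import datetime, timezone
from fractions import Fraction
from importlib import resources as importlib_resources
from typing import Iterable, Mapping, Optional, Sequence

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import DCAT, DCTERMS, PROV, RDF, SKOS, XSD

from .metrics import METRIC_IDS, MetricResult

DQV = Namespace("http://www.w3.org/ns/dqv#")
FQM = Namespace("http://purl.org/fqm#")

#: Metric URIs in the FQM namespace.  Only the non-resolvable and
#: undefined names are fixed by the vocabulary; the others follow the
#: same style and can be remapped through this table without code
#: change.
DEFAULT_METRIC_URIS: dict[str, URIRef] = {
    "non_resolvable_uris": FQM.uriNonResolvableMetric,
    "non_parsable_uris": FQM.uriNonParsableMetric,
    "undefined_uris": FQM.uriUndefinedMetric,
    "misplaced_classes_or_properties": FQM.misplacedClassOrPropertyMetric,
    "misused_datatype_or_object_property": FQM.misusedPropertyTypeMetric,
    "deprecated_classes_or_properties": FQM.deprecatedClassOrPropertyMetric,
}

#: Human-readable definitions attached to the metric URIs via
#: skos:definition, for the third quality question.
METRIC_DEFINITIONS: dict[str, str] = {
    "non_resolvable_uris": (
        "Proportion of unique non-resolvable URIs (final HTTP status in "
        "the 4xx or 5xx range) among all unique URIs of the resource."
    ),
    "non_parsable_uris": (
        "Proportion of unique URIs whose response declares an RDF media "
        "type but does not parse to at least one triple, among all "
        "unique URIs."
    ),
    "undefined_uris": (
        "Proportion of unique URIs that do not occur in the RDF triples "
        "retrieved by resolving them, among all unique URIs."
    ),
    "misplaced_classes_or_properties": (
        "Proportion of classes used in the predicate position, or "
        "properties used in the object position of non-defining triples, "
        "among all unique classes and properties."
    ),
    "misused_datatype_or_object_property": (
        "Proportion of owl:DatatypeProperty properties used with a URI "
        "object, or owl:ObjectProperty properties used with a literal "
        "object, among all unique properties."
    ),
    "deprecated_classes_or_properties": (
        "Proportion of deprecated classes or properties in use, among "
        "all unique classes and properties."
    ),
}


def _measurement_node(resource_id: str, metric_id: str) -> URIRef:
    digest = hashlib.sha1(
        f"{resource_id}\x00{metric_id}".encode()
    ).hexdigest()[:16]
    return URIRef(f"urn:rdfqa:measurement:{digest}")


def _bind_namespaces(graph: Graph) -> None:
    graph.bind("dqv", DQV)
    graph.bind("fqm", FQM)
    graph.bind("dcat", DCAT)
    graph.bind("dcterms", DCTERMS)
    graph.bind("prov", PROV)
    graph.bind("skos", SKOS)


def build_report(
    resource_id: str,
    results: Sequence[MetricResult],
    generated_at: Optional[datetime] = None,
    failures_only: bool = False,
    metric_uris: Mapping[str, URIRef] = DEFAULT_METRIC_URIS,
) -> Graph:
    """Build the DQV assessment report graph for one resource.

    By default every metric gets a measurement node (value ``"0/N"``
    when it passes), so the report also records which metrics were
    tested; ``failures_only`` restricts the report to failed metrics.
    """
    if generated_at is None:
        generated_at = datetime.now(timezone.utc)
    stamp = Literal(generated_at.isoformat(), datatype=XSD.dateTime)
    graph = Graph()
    _bind_namespaces(graph)
    resource = URIRef(resource_id)
    graph.add((resource, RDF.type, DCAT.Resource))
    for result in results:
        if failures_only and result.numerator == 0:
            continue
        node = _measurement_node(resource_id, result.metric_id)
        graph.add((resource, DQV.hasQualityMeasurement, node))
        graph.add((node, RDF.type, DQV.QualityMeasurement))
        graph.add((node, DQV.computedOn, resource))
        graph.add((node, DQV.isMeasurementOf, metric_uris[result.metric_id]))
        graph.add((node, DQV.value, Literal(result.value)))
        graph.add((node, PROV.generatedAtTime, stamp))
        for uri in result.error_uris:
            graph.add((node, DCTERMS.relation, URIRef(uri)))
    return graph


def fqm_definitions_graph(
    metric_uris: Mapping[str, URIRef] = DEFAULT_METRIC_URIS,
) -> Graph:
    """Metric nodes with their skos:definition strings."""
    graph = Graph()
    _bind_namespaces(graph)
    for metric_id in METRIC_IDS:
        node = metric_uris[metric_id]
        graph.add((node, RDF.type, DQV.Metric))
        graph.add(
            (node, SKOS.definition, Literal(METRIC_DEFINITIONS[metric_id]))
        )
    return graph


_QUERY_FILES = {
    1: "q1_nonresolvable_over_10pct.rq",
    2: "q2_undefined_uris.rq",
    3: "q3_issues_with_definitions.rq",
}


def load_query(question: int) -> str:
    """Return the bundled SPARQL text for question 1, 2, or 3."""
    try:
        name = _QUERY_FILES[question]
    except KeyError:
        raise ValueError(f"question must be 1, 2, or 3, got {question!r}")
    return (
        importlib_resources.files("rdfqa") / "queries" / name
    ).read_text(encoding="utf-8")


def run_quality_query(
    report_graphs: Iterable[Graph],
    question: int,
    resource: Optional[str] = None,
) -> list[tuple]:
    """Run one of the three quality questions over a set of reports.

    Question 3 asks about a single resource; pass it as ``resource``.
    Reports are merged into one in-memory store; question 3 additionally
    loads the metric definitions so ``skos:definition`` resolves.
    """
    store = Graph()
    _bind_namespaces(store)
    for graph in report_graphs:
        store += graph
    init_bindings = None
    if question == 3:
        store += fqm_definitions_graph()
        if resource is not None:
            init_bindings = {"resource": URIRef(resource)}
    result = store.query(load_query(question), initBindings=init_bindings)
    return [tuple(row) for row in result]


def parse_value_fraction(value: str) -> Fraction:
    """Parse a ``dqv:value`` lexical fraction ``"n/N"`` exactly."""
    numerator, _, denominator = value.partition("/")
    d = int(denominator)
    if d == 0:
        return Fraction(0)
    return Fraction(int(numerator), d)
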