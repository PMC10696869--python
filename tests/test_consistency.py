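"""Term typing, deprecation, misplacement, and property-flavor misuse."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from rdfqa import (
    ErrorKind,
    Flavor,
    OfflineTransport,
    assess_document,
    check_deprecated,
    forge_resource,
)
from rdfqa.consistency import (
    DEFAULT_DEFINING_PREDICATES,
    find_misplaced_classes,
    find_misplaced_properties,
    find_misused_property_flavors,
    type_term,
)
from rdfqa.forge import random_spec

from conftest import turtle_doc

EX = "http://x.invalid/"


def graph_of(*triples):
    g = Graph()
    for t in triples:
        g.add(t)
    return g


class TestTyping:
    def test_object_property_flavor(self):
        uri = f"{EX}p"
        g = graph_of((URIRef(uri), RDF.type, OWL.ObjectProperty))
        t = type_term(uri, g)
        assert t.is_property and t.flavor is Flavor.OBJECT

    def test_named_individual_exempt_from_consistency(self):
        uri = f"{EX}instance"
        g = graph_of((URIRef(uri), RDF.type, OWL.NamedIndividual))
        t = type_term(uri, g)
        assert t.is_named_individual
        assert not t.consistency_applicable

    def test_double_class_typing_is_idempotent(self):
        uri = f"{EX}c"
        g = graph_of(
            (URIRef(uri), RDF.type, OWL.Class),
            (URIRef(uri), RDF.type, RDFS.Class),
        )
        t = type_term(uri, g)
        assert t.is_class and not t.is_property

    def test_punned_term_is_both_class_and_property(self):
        uri = f"{EX}both"
        g = graph_of(
            (URIRef(uri), RDF.type, OWL.Class),
            (URIRef(uri), RDF.type, OWL.ObjectProperty),
        )
        t = type_term(uri, g)
        assert t.is_class and t.is_property and t.flavor is Flavor.OBJECT


class TestDeprecation:
    """The four deprecation triple patterns, and near-misses."""

    @pytest.mark.parametrize(
        "typing_triple,deprecation_triple",
        [
            # boolean-flag pattern on a class and on a property
            ((RDF.type, OWL.Class),
             (OWL.deprecated, Literal("true", datatype=XSD.boolean))),
            ((RDF.type, RDF.Property),
             (OWL.deprecated, Literal("true", datatype=XSD.boolean))),
            # typing pattern
            ((RDF.type, OWL.DeprecatedClass), None),
            ((RDF.type, OWL.DeprecatedProperty), None),
        ],
    )
    def test_each_pattern_deprecates(self, typing_triple, deprecation_triple):
        uri = f"{EX}term"
        triples = [(URIRef(uri), *typing_triple)]
        if deprecation_triple:
            triples.append((URIRef(uri), *deprecation_triple))
        assert check_deprecated(uri, graph_of(*triples))

    @pytest.mark.parametrize(
        "obj",
        [
            Literal("false", datatype=XSD.boolean),
            Literal("true"),              # untyped literal
            Literal("true", lang="en"),
            Literal(1),                   # integer, not boolean
        ],
    )
    def test_near_miss_objects_do_not_deprecate(self, obj):
        uri = f"{EX}term"
        g = graph_of(
            (URIRef(uri), RDF.type, OWL.Class),
            (URIRef(uri), OWL.deprecated, obj),
        )
        assert not check_deprecated(uri, g)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        pattern=st.sampled_from(["bool_class", "bool_prop", "type_class",
                                 "type_prop"]),
        truthy=st.booleans(),
        typed=st.booleans(),
    )
    def test_only_exact_patterns_flip_deprecation(self, pattern, truthy, typed):
        uri = f"{EX}term"
        ref = URIRef(uri)
        if pattern.startswith("bool"):
            base_type = OWL.Class if pattern == "bool_class" else RDF.Property
            lexical = "true" if truthy else "false"
            literal = (Literal(lexical, datatype=XSD.boolean) if typed
                       else Literal(lexical))
            g = graph_of((ref, RDF.type, base_type),
                         (ref, OWL.deprecated, literal))
            assert check_deprecated(uri, g) == (truthy and typed)
        else:
            marker = (OWL.DeprecatedClass if pattern == "type_class"
                      else OWL.DeprecatedProperty)
            g = graph_of((ref, RDF.type, marker))
            assert check_deprecated(uri, g)


def typings_from_definitions(**defs):
    """Build typings from per-URI definition graphs."""
    return {uri: type_term(uri, graph) for uri, graph in defs.items()}


class TestMisplacement:
    def test_class_used_as_predicate_is_misplaced(self):
        cls = f"{EX}Catalog"
        typings = typings_from_definitions(
            **{cls: graph_of((URIRef(cls), RDF.type, OWL.Class))}
        )
        doc = turtle_doc(f"<{EX}s> <{cls}> <{EX}o> .")
        errors = find_misplaced_classes(doc, typings)
        assert [e.uri for e in errors] == [cls]
        assert errors[0].kind is ErrorKind.MISPLACED_CLASS
        assert errors[0].witness_triple in list(doc.triples())

    def test_class_as_subject_or_object_is_fine(self):
        cls = f"{EX}Catalog"
        typings = typings_from_definitions(
            **{cls: graph_of((URIRef(cls), RDF.type, OWL.Class))}
        )
        doc = turtle_doc(f"<{cls}> <{EX}p> <{cls}> .")
        assert find_misplaced_classes(doc, typings) == []

    def test_property_as_object_of_defining_triple_is_fine(self):
        prop = f"{EX}p"
        typings = typings_from_definitions(
            **{prop: graph_of((URIRef(prop), RDF.type, OWL.ObjectProperty))}
        )
        doc = turtle_doc(
            f"<{prop}> <http://www.w3.org/1999/02/22-rdf-syntax-ns#type> "
            f"<http://www.w3.org/2002/07/owl#ObjectProperty> ."
        )
        assert find_misplaced_properties(doc, typings) == []

    def test_property_as_object_of_ordinary_triple_is_misplaced(self):
        prop = f"{EX}p"
        typings = typings_from_definitions(
            **{prop: graph_of((URIRef(prop), RDF.type, OWL.ObjectProperty))}
        )
        doc = turtle_doc(f"<{EX}s> <{EX}uses> <{prop}> .")
        errors = find_misplaced_properties(doc, typings)
        assert [e.uri for e in errors] == [prop]

    def test_exempting_a_predicate_removes_exactly_its_errors(self):
        prop = f"{EX}p"
        typings = typings_from_definitions(
            **{prop: graph_of((URIRef(prop), RDF.type, OWL.ObjectProperty))}
        )
        doc = turtle_doc(
            f"<{EX}s1> <{EX}uses> <{prop}> .\n"
            f"<{EX}s2> <{EX}mentions> <{prop}> ."
        )
        baseline = find_misplaced_properties(doc, typings)
        assert len(baseline) == 2
        extended = DEFAULT_DEFINING_PREDICATES | {URIRef(f"{EX}uses")}
        remaining = find_misplaced_properties(doc, typings, extended)
        assert [e.witness_triple[1] for e in remaining] == [URIRef(f"{EX}mentions")]


class TestMisuse:
    """Range discipline of declared Datatype/Object properties.

    The worked examples mirror two published misuse findings: a
    dcat:mediaType triple with the string "application/zip", and a
    skos:closeMatch triple whose object is a quoted URI (hence a string
    literal) - both predicates declared owl:ObjectProperty.
    """

    MEDIA_TYPE = "http://www.w3.org/ns/dcat#mediaType"
    CLOSE_MATCH = "http://www.w3.org/2004/02/skos/core#closeMatch"

    def object_property_typings(self, *uris):
        return typings_from_definitions(
            **{u: graph_of((URIRef(u), RDF.type, OWL.ObjectProperty))
               for u in uris}
        )

    def test_object_property_with_literal_is_misused(self):
        typings = self.object_property_typings(self.MEDIA_TYPE)
        doc = turtle_doc(
            f"<http://data.wikipathways.org/20220410/rdf/wp> "
            f"<{self.MEDIA_TYPE}> \"application/zip\" ."
        )
        errors = find_misused_property_flavors(doc, typings)
        assert [(e.kind, e.uri) for e in errors] == [
            (ErrorKind.MISUSED_OBJECT_PROPERTY, self.MEDIA_TYPE)
        ]

    def test_quoted_uri_is_a_string_and_misused(self):
        typings = self.object_property_typings(self.CLOSE_MATCH)
        doc = turtle_doc(
            f"<http://purl.obolibrary.org/obo/RO_0002436> <{self.CLOSE_MATCH}> "
            f"\"http://purl.obolibrary.org/obo/MI_0915\" ."
        )
        errors = find_misused_property_flavors(doc, typings)
        assert [e.uri for e in errors] == [self.CLOSE_MATCH]

    def test_real_uri_object_clears_the_flag(self):
        typings = self.object_property_typings(self.CLOSE_MATCH)
        doc = turtle_doc(
            f"<http://purl.obolibrary.org/obo/RO_0002436> <{self.CLOSE_MATCH}> "
            f"<http://purl.obolibrary.org/obo/MI_0915> ."
        )
        assert find_misused_property_flavors(doc, typings) == []

    def test_datatype_property_with_uri_object_is_misused(self):
        prop = f"{EX}dtp"
        typings = typings_from_definitions(
            **{prop: graph_of((URIRef(prop), RDF.type, OWL.DatatypeProperty))}
        )
        doc = turtle_doc(f"<{EX}s> <{prop}> <{EX}o> .")
        errors = find_misused_property_flavors(doc, typings)
        assert [e.kind for e in errors] == [ErrorKind.MISUSED_DATATYPE_PROPERTY]

    def test_blank_node_object_triggers_neither_rule(self):
        dtp, objp = f"{EX}dtp", f"{EX}objp"
        typings = typings_from_definitions(
            **{
                dtp: graph_of((URIRef(dtp), RDF.type, OWL.DatatypeProperty)),
                objp: graph_of((URIRef(objp), RDF.type, OWL.ObjectProperty)),
            }
        )
        doc_graph = graph_of(
            (URIRef(f"{EX}s"), URIRef(dtp), BNode("b1")),
            (URIRef(f"{EX}s"), URIRef(objp), BNode("b2")),
        )
        from rdfqa.inventory import document_from_graph

        assert find_misused_property_flavors(
            document_from_graph(doc_graph), typings) == []

    def test_annotation_property_is_exempt(self):
        prop = f"{EX}note"
        typings = typings_from_definitions(
            **{prop: graph_of((URIRef(prop), RDF.type, OWL.AnnotationProperty))}
        )
        doc = turtle_doc(f"<{EX}s> <{prop}> \"free text\" .\n"
                         f"<{EX}s> <{prop}> <{EX}o> .")
        assert find_misused_property_flavors(doc, typings) == []


class TestLedgerAgreement:
    @pytest.mark.parametrize("seed", [31, 32, 33, 34, 35])
    def test_each_error_category_count_matches_injection(self, seed):
        result = forge_resource(random_spec(seed, max_uris=80))
        assessment = assess_document(
            result.document, OfflineTransport(result.fixture_map, strict=True))
        by_kind = {}
        for error in assessment.consistency_errors:
            by_kind.setdefault(error.kind, set()).add(error.uri)
        expectations = {
            ErrorKind.MISPLACED_CLASS: "misplaced_class",
            ErrorKind.MISPLACED_PROPERTY: "misplaced_property",
            ErrorKind.MISUSED_DATATYPE_PROPERTY: "misused_datatype",
            ErrorKind.MISUSED_OBJECT_PROPERTY: "misused_object",
            ErrorKind.DEPRECATED_CLASS: "deprecated_class",
            ErrorKind.DEPRECATED_PROPERTY: "deprecated_property",
        }
        for kind, category in expectations.items():
            assert by_kind.get(kind, set()) == set(
                result.ledger.injected[category]), (seed, kind)

    def test_witness_triples_occur_in_the_document(self):
        result = forge_resource(random_spec(36, max_uris=60))
        assessment = assess_document(
            result.document, OfflineTransport(result.fixture_map, strict=True))
        doc_triples = set(result.document.triples())
        for error in assessment.consistency_errors:
            assert error.witness_triple in doc_triples
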