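"""Consistency checks on defined terms: typing, deprecation, placement,
and DatatypeProperty/ObjectProperty range discipline.

A term's typing is read only from its *definition* graph (the triples
retrieved by resolving it), never from the assessed document.  The
assessed document is then scanned for:

* misplaced classes — a class used in the predicate slot;
* misplaced properties — a property used in the object slot of a
  non-defining triple;
* misused owl:DatatypeProperty (URI object) / owl:ObjectProperty
  (literal object);
* use of deprecated classes or properties.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import DCTERMS, OWL, RDF, RDFS, XSD

from .definitions import Stage, UriVerdict
from .inventory import SourceDocument

#: rdf:Property plus every OWL property type.  owl:DeprecatedProperty is
#: also a property type in the OWL vocabulary.  Config-visible because
#: "any OWL property" is open-ended.
OWL_PROPERTY_TYPES: frozenset[URIRef] = frozenset(
    {
        RDF.Property,
        OWL.ObjectProperty,
        OWL.DatatypeProperty,
        OWL.AnnotationProperty,
        OWL.FunctionalProperty,
        OWL.InverseFunctionalProperty,
        OWL.TransitiveProperty,
        OWL.SymmetricProperty,
        OWL.AsymmetricProperty,
        OWL.ReflexiveProperty,
        OWL.IrreflexiveProperty,
        OWL.OntologyProperty,
        OWL.DeprecatedProperty,
    }
)

#: owl:DeprecatedClass is a subclass of rdfs:Class in the OWL vocabulary,
#: so typing a term with it makes the term a class (and deprecated).
CLASS_TYPES: frozenset[URIRef] = frozenset(
    {OWL.Class, RDFS.Class, OWL.DeprecatedClass}
)

#: Predicates whose object slot legitimately holds a property (triples
#: that define or relate terms rather than use them).  Overridable.
DEFAULT_DEFINING_PREDICATES: frozenset[URIRef] = frozenset(
    {
        RDF.type,
        RDFS.subPropertyOf,
        OWL.onProperty,
        OWL.equivalentProperty,
        OWL.inverseOf,
        OWL.propertyDisjointWith,
        RDFS.seeAlso,
        DCTERMS.relation,
    }
)


class Flavor(str, enum.Enum):
    DATATYPE = "datatype"
    OBJECT = "object"
    ANNOTATION = "annotation"
    OTHER = "other"
    NONE = "none"


class ErrorKind(str, enum.Enum):
    MISPLACED_CLASS = "misplaced_class"
    MISPLACED_PROPERTY = "misplaced_property"
    MISUSED_DATATYPE_PROPERTY = "misused_datatype_property"
    MISUSED_OBJECT_PROPERTY = "misused_object_property"
    DEPRECATED_CLASS = "deprecated_class"
    DEPRECATED_PROPERTY = "deprecated_property"


@dataclass(frozen=True)
class TermTyping:
    """Typing of one defined URI, derived from its definition graph."""

    uri: str
    is_class: bool
    is_property: bool
    flavor: Flavor
    deprecated: bool
    is_named_individual: bool

    @property
    def consistency_applicable(self) -> bool:
        """NamedIndividuals that are neither class nor property are only
        assessed for resolvability and parsability."""
        if self.is_named_individual and not (self.is_class or self.is_property):
            return False
        return self.is_class or self.is_property


@dataclass(frozen=True)
class ConsistencyError:
    kind: ErrorKind
    uri: str
    witness_triple: tuple

    def witness_ntriples(self) -> str:
        return " ".join(t.n3() for t in self.witness_triple) + " ."


def check_deprecated(uri: str, retrieved_graph: Graph) -> bool:
    """True iff one of the four deprecation triple patterns matches.

    ``T owl:deprecated "true"^^xsd:boolean`` (for a class or a property),
    ``C rdf:type owl:DeprecatedClass``, or ``P rdf:type
    owl:DeprecatedProperty``.  A plain (untyped) ``"true"`` literal or a
    boolean ``"false"`` does not deprecate.
    """
    ref = URIRef(uri)
    for obj in retrieved_graph.objects(ref, OWL.deprecated):
        if (
            isinstance(obj, Literal)
            and obj.datatype == XSD.boolean
            and obj.toPython() is True
        ):
            return True
    for cls in retrieved_graph.objects(ref, RDF.type):
        if cls in (OWL.DeprecatedClass, OWL.DeprecatedProperty):
            return True
    return False


def type_term(
    uri: str,
    retrieved_graph: Graph,
    owl_property_types: frozenset[URIRef] = OWL_PROPERTY_TYPES,
) -> TermTyping:
    ref = URIRef(uri)
    types = set(retrieved_graph.objects(ref, RDF.type))
    is_class = bool(types & CLASS_TYPES)
    is_property = bool(types & owl_property_types)
    if OWL.DatatypeProperty in types:
        flavor = Flavor.DATATYPE
    elif OWL.ObjectProperty in types:
        flavor = Flavor.OBJECT
    elif OWL.AnnotationProperty in types:
        flavor = Flavor.ANNOTATION
    elif is_property:
        flavor = Flavor.OTHER
    else:
        flavor = Flavor.NONE
    deprecated = (
        check_deprecated(uri, retrieved_graph) if (is_class or is_property) else False
    )
    return TermTyping(
        uri=uri,
        is_class=is_class,
        is_property=is_property,
        flavor=flavor,
        deprecated=deprecated,
        is_named_individual=OWL.NamedIndividual in types,
    )


def type_terms(
    verdicts: Mapping[str, UriVerdict],
    owl_property_types: frozenset[URIRef] = OWL_PROPERTY_TYPES,
) -> dict[str, TermTyping]:
    """Extract typings for every defined URI."""
    return {
        uri: type_term(uri, v.retrieved_graph, owl_property_types)
        for uri, v in verdicts.items()
        if v.stage is Stage.DEFINED and v.retrieved_graph is not None
    }


def _applicable(typings: Mapping[str, TermTyping]) -> dict[str, TermTyping]:
    return {u: t for u, t in typings.items() if t.consistency_applicable}


def find_misplaced_classes(
    doc: SourceDocument, typings: Mapping[str, TermTyping]
) -> list[ConsistencyError]:
    """A class used as the predicate of a triple is misplaced."""
    classes = {u for u, t in _applicable(typings).items() if t.is_class}
    errors = []
    for s, p, o in doc.triples():
        if isinstance(p, URIRef) and str(p) in classes:
            errors.append(
                ConsistencyError(ErrorKind.MISPLACED_CLASS, str(p), (s, p, o))
            )
    return errors


def find_misplaced_properties(
    doc: SourceDocument,
    typings: Mapping[str, TermTyping],
    defining_predicates: Iterable[URIRef] = DEFAULT_DEFINING_PREDICATES,
) -> list[ConsistencyError]:
    """A property in the object slot is misplaced, unless the triple's
    predicate is a defining predicate (rdf:type, rdfs:subPropertyOf, ...)."""
    defining = frozenset(defining_predicates)
    properties = {u for u, t in _applicable(typings).items() if t.is_property}
    errors = []
    for s, p, o in doc.triples():
        if p in defining:
            continue
        if isinstance(o, URIRef) and str(o) in properties:
            errors.append(
                ConsistencyError(ErrorKind.MISPLACED_PROPERTY, str(o), (s, p, o))
            )
    return errors


def find_misused_property_flavors(
    doc: SourceDocument, typings: Mapping[str, TermTyping]
) -> list[ConsistencyError]:
    """Range-discipline check on correctly-placed properties.

    A DatatypeProperty predicate with a URI object, or an ObjectProperty
    predicate with a literal object, is misused.  Blank-node objects are
    neither URIs nor literals and trigger no error.
    """
    flavors = {
        u: t.flavor
        for u, t in _applicable(typings).items()
        if t.flavor in (Flavor.DATATYPE, Flavor.OBJECT)
    }
    errors = []
    for s, p, o in doc.triples():
        flavor = flavors.get(str(p)) if isinstance(p, URIRef) else None
        if flavor is None:
            continue
        if flavor is Flavor.DATATYPE and isinstance(o, URIRef):
            errors.append(
                ConsistencyError(
                    ErrorKind.MISUSED_DATATYPE_PROPERTY, str(p), (s, p, o)
                )
            )
        elif flavor is Flavor.OBJECT and isinstance(o, Literal):
            errors.append(
                ConsistencyError(
                    ErrorKind.MISUSED_OBJECT_PROPERTY, str(p), (s, p, o)
                )
            )
    return errors


def find_deprecated_terms(
    doc: SourceDocument, typings: Mapping[str, TermTyping]
) -> list[ConsistencyError]:
    """Deprecated classes/properties used by the assessed document.

    The witness is the first document triple (in graph iteration order)
    in which the deprecated term occurs.
    """
    deprecated = {
        u: t for u, t in _applicable(typings).items() if t.deprecated
    }
    witnesses: dict[str, tuple] = {}
    for triple in doc.triples():
        for term in triple:
            if isinstance(term, URIRef) and str(term) in deprecated:
                witnesses.setdefault(str(term), triple)
    errors = []
    for uri in sorted(deprecated):
        if uri not in witnesses:
            continue
        t = deprecated[uri]
        kind = (
            ErrorKind.DEPRECATED_CLASS if t.is_class else ErrorKind.DEPRECATED_PROPERTY
        )
        errors.append(ConsistencyError(kind, uri, witnesses[uri]))
    return errors


def find_all_consistency_errors(
    doc: SourceDocument,
    typings: Mapping[str, TermTyping],
    defining_predicates: Iterable[URIRef] = DEFAULT_DEFINING_PREDICATES,
) -> list[ConsistencyError]:
    return (
        find_misplaced_classes(doc, typings)
        + find_misplaced_properties(doc, typings, defining_predicates)
        + find_misused_property_flavors(doc, typings)
        + find_deprecated_terms(doc, typings)
    )
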