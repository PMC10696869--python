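"""Synthetic RDF resources with controlled, ledgered error injection.

``forge_resource`` builds, from a :class:`ForgeSpec`, three artifacts
that together make the whole assessment pipeline testable offline:

* an RDF document containing a requested number of unique URIs,
  literal occurrences, blank nodes, and (optionally) total triples;
* an offline HTTP fixture map answering every URI of the document, with
  each error category injected per its defining condition (404 for
  non-resolvable, RDF media type + garbage for non-parsable, a graph
  omitting the URI for undefined, flavor-declaring definition graphs
  plus a violating document triple for the misuse categories, the
  deprecation triple patterns for deprecated terms);
* a ledger stating exactly what a correct assessor must report —
  per-category URI sets, witness triples, the component inventory, and
  all six expected metric results.

Generation is a pure function of the spec: the seed drives URI naming
and triple placement, while category assignment is deterministic-first
(injections occupy the leading URI indices) so ledgers stay stable
under small spec edits.  Forged URIs live under a reserved,
non-registrable base so accidental live HTTP can never succeed.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from typing import Optional

from rdflib import BNode, Graph, Literal, URIRef

from .inventory import ComponentInventory, SourceDocument, extract_components
from .resolution import RDF_MEDIA_TYPES

DEFAULT_BASE = "http://fixture.invalid/"

_RDFS_LABEL = "http://www.w3.org/2000/01/rdf-schema#label"
_RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
_OWL = "http://www.w3.org/2002/07/owl#"

#: Injection categories in their deterministic assignment order.
CATEGORIES: tuple[str, ...] = (
    "non_resolvable",
    "non_rdf_content",
    "non_parsable",
    "undefined",
    "misplaced_class",
    "misplaced_property",
    "misused_datatype",
    "misused_object",
    "deprecated_class",
    "deprecated_property",
)


class InfeasibleSpecError(ValueError):
    """The requested counts cannot be realized in one document."""


@dataclass(frozen=True)
class ForgeSpec:
    """Recipe for one synthetic resource.

    ``n_uris`` is the total number of unique URIs in the document,
    injected categories included; at least two URIs beyond the
    injections are required (one filler predicate, one filler term).
    ``n_literals`` counts literal occurrences and must cover one literal
    per ``misused_object`` injection.  ``n_triples``, when given, is an
    exact total the document is padded to.
    """

    seed: int = 0
    n_uris: int = 20
    non_resolvable: int = 0
    non_rdf_content: int = 0
    non_parsable: int = 0
    undefined: int = 0
    misplaced_class: int = 0
    misplaced_property: int = 0
    misused_datatype: int = 0
    misused_object: int = 0
    deprecated_class: int = 0
    deprecated_property: int = 0
    n_literals: int = 0
    n_blank_nodes: int = 0
    n_triples: Optional[int] = None
    base: str = DEFAULT_BASE

    def count(self, category: str) -> int:
        return getattr(self, category)

    @property
    def total_injections(self) -> int:
        return sum(self.count(c) for c in CATEGORIES)

    def validate(self) -> None:
        for name in CATEGORIES + ("n_uris", "n_literals", "n_blank_nodes"):
            if getattr(self, name) < 0:
                raise InfeasibleSpecError(f"{name} must be non-negative")
        if self.total_injections + 2 > self.n_uris:
            raise InfeasibleSpecError(
                f"n_uris={self.n_uris} cannot hold {self.total_injections} "
                "injections plus the filler predicate and one filler term"
            )
        if self.n_literals < self.misused_object:
            raise InfeasibleSpecError(
                "each misused_object injection consumes one literal; "
                f"n_literals={self.n_literals} < {self.misused_object}"
            )

    @classmethod
    def from_json(cls, path: str) -> "ForgeSpec":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class ExpectedMetric:
    error_uris: tuple[str, ...]
    numerator: int
    denominator: int
    affected_triples: int
    total_triples: int


@dataclass
class ForgeLedger:
    """Exactly what a correct assessor must report on the forged resource."""

    injected: dict[str, tuple[str, ...]]
    witness_triples: dict[str, tuple[str, ...]]
    inventory: ComponentInventory
    expected_metrics: dict[str, ExpectedMetric]

    def to_json_dict(self) -> dict:
        return {
            "injected": {k: list(v) for k, v in self.injected.items()},
            "witness_triples": {
                k: list(v) for k, v in self.witness_triples.items()
            },
            "inventory": {
                "n_uris": self.inventory.n_uris,
                "n_literals": self.inventory.n_literals,
                "n_blank_nodes": self.inventory.n_blank_nodes,
                "n_triples": self.inventory.n_triples,
            },
            "expected_metrics": {
                k: dataclasses.asdict(v) for k, v in self.expected_metrics.items()
            },
        }


@dataclass
class ForgeResult:
    document: SourceDocument
    fixture_map: dict[str, dict]
    ledger: ForgeLedger
    spec: ForgeSpec = field(repr=False, default=None)


def _turtle(triples: str) -> dict:
    return {"status": 200, "content_type": "text/turtle", "body": triples}


def _definition_body(uri: str, extra: str = "") -> str:
    return f'<{uri}> <{_RDFS_LABEL}> "forged term" .\n{extra}'


def forge_resource(spec: ForgeSpec) -> ForgeResult:
    """Generate document, fixture map, and ledger for a spec.

    Raises :class:`InfeasibleSpecError` when the counts cannot be met.
    """
    spec.validate()
    rng = random.Random(spec.seed)

    # local names start with a letter so the document also serializes
    # under QName-based formats such as RDF/XML
    names = [
        f"{spec.base}term/t{i:04d}x{rng.getrandbits(16):04x}"
        for i in range(spec.n_uris)
    ]
    injected: dict[str, tuple[str, ...]] = {}
    cursor = 0
    for category in CATEGORIES:
        n = spec.count(category)
        injected[category] = tuple(names[cursor:cursor + n])
        cursor += n
    predicate = names[cursor]
    fillers = names[cursor + 1:]

    pick = lambda: rng.choice(fillers)  # noqa: E731 - local shorthand
    p = URIRef(predicate)

    triples: list[tuple] = []
    witness: dict[str, list[tuple]] = {c: [] for c in CATEGORIES}

    def add(category: Optional[str], s, pr, o) -> None:
        triples.append((s, pr, o))
        if category is not None:
            witness[category].append((s, pr, o))

    for category in ("non_resolvable", "non_rdf_content", "non_parsable",
                     "undefined", "deprecated_class"):
        for uri in injected[category]:
            add(category, URIRef(uri), p, URIRef(pick()))
    for uri in injected["deprecated_property"]:
        add("deprecated_property", URIRef(pick()), URIRef(uri), URIRef(pick()))
    for uri in injected["misplaced_class"]:
        add("misplaced_class", URIRef(pick()), URIRef(uri), URIRef(pick()))
    for uri in injected["misplaced_property"]:
        add("misplaced_property", URIRef(pick()), p, URIRef(uri))
    for uri in injected["misused_datatype"]:
        add("misused_datatype", URIRef(pick()), URIRef(uri), URIRef(pick()))
    for i, uri in enumerate(injected["misused_object"]):
        add("misused_object", URIRef(pick()), URIRef(uri),
            Literal(f"{spec.base}looks-like-a-uri/{i}"))

    covered = {str(t) for triple in triples for t in triple
               if isinstance(t, URIRef)}
    uncovered = [f for f in fillers if f not in covered]

    def next_subject() -> URIRef:
        if uncovered:
            return URIRef(uncovered.pop(0))
        return URIRef(pick())

    for k in range(spec.n_literals - spec.misused_object):
        add(None, next_subject(), p, Literal(f"filler literal {k}"))
    for k in range(spec.n_blank_nodes):
        add(None, next_subject(), p, BNode(f"b{k}"))
    pair_pool: set[tuple[str, str]] = {
        (str(s), str(o)) for s, pr, o in triples
        if pr == p and isinstance(o, URIRef)
    }
    while uncovered:
        a = uncovered.pop(0)
        b = uncovered.pop(0) if uncovered else pick()
        if a == b and len(fillers) > 1:
            b = fillers[0] if fillers[0] != a else fillers[1]
        add(None, URIRef(a), p, URIRef(b))
        pair_pool.add((a, b))

    if spec.n_triples is not None:
        if len(triples) > spec.n_triples:
            raise InfeasibleSpecError(
                f"spec requires at least {len(triples)} triples, "
                f"n_triples={spec.n_triples}"
            )
        shortfall = spec.n_triples - len(triples)
        candidates = (
            (a, b) for a in fillers for b in fillers
            if a != b and (a, b) not in pair_pool
        )
        for _ in range(shortfall):
            try:
                a, b = next(candidates)
            except StopIteration:
                raise InfeasibleSpecError(
                    "not enough filler URI pairs to pad to "
                    f"n_triples={spec.n_triples}"
                )
            add(None, URIRef(a), p, URIRef(b))
            pair_pool.add((a, b))

    graph = Graph()
    for s, pr, o in triples:
        graph.add((s, pr, o))
    assert len(graph) == len(triples), "duplicate triple generated"
    document = SourceDocument(
        identifier=f"urn:rdfqa:forged:{spec.seed}",
        serialization="turtle",
        graph=graph,
    )

    fixture_map = _build_fixture_map(spec, rng, injected, predicate, fillers)
    ledger = _build_ledger(spec, injected, witness, document)
    return ForgeResult(document=document, fixture_map=fixture_map,
                       ledger=ledger, spec=spec)


def _build_fixture_map(spec, rng, injected, predicate, fillers) -> dict:
    fixture: dict[str, dict] = {}
    void = f"<{spec.base}void/x> <{spec.base}void/p> \"nothing here\" ."
    for uri in injected["non_resolvable"]:
        fixture[uri] = {
            "status": rng.choice([404, 410, 423, 500, 503]),
            "content_type": "text/plain",
            "body": "error",
        }
    for uri in injected["non_rdf_content"]:
        fixture[uri] = {
            "status": 200,
            "content_type": rng.choice(
                ["text/html", "application/json", "application/pdf"]
            ),
            "body": "<html><body>not rdf</body></html>",
        }
    for uri in injected["non_parsable"]:
        fixture[uri] = {
            "status": 200,
            "content_type": rng.choice(sorted(RDF_MEDIA_TYPES)),
            "body": rng.choice(["@!$ this is not RDF %^&", ""]),
        }
    for uri in injected["undefined"]:
        fixture[uri] = _turtle(void)
    for uri in injected["misplaced_class"]:
        fixture[uri] = _turtle(f"<{uri}> <{_RDF_TYPE}> <{_OWL}Class> .")
    for uri in injected["misplaced_property"]:
        cls = rng.choice(["Property", "ObjectProperty"])
        ns = (_OWL if cls == "ObjectProperty"
              else "http://www.w3.org/1999/02/22-rdf-syntax-ns#")
        fixture[uri] = _turtle(f"<{uri}> <{_RDF_TYPE}> <{ns}{cls}> .")
    for uri in injected["misused_datatype"]:
        fixture[uri] = _turtle(
            f"<{uri}> <{_RDF_TYPE}> <{_OWL}DatatypeProperty> ."
        )
    for uri in injected["misused_object"]:
        fixture[uri] = _turtle(
            f"<{uri}> <{_RDF_TYPE}> <{_OWL}ObjectProperty> ."
        )
    for uri in injected["deprecated_class"]:
        if rng.random() < 0.5:
            body = (
                f"<{uri}> <{_RDF_TYPE}> <{_OWL}Class> .\n"
                f"<{uri}> <{_OWL}deprecated> "
                '"true"^^<http://www.w3.org/2001/XMLSchema#boolean> .'
            )
        else:
            body = f"<{uri}> <{_RDF_TYPE}> <{_OWL}DeprecatedClass> ."
        fixture[uri] = _turtle(body)
    for uri in injected["deprecated_property"]:
        if rng.random() < 0.5:
            body = (
                f"<{uri}> <{_RDF_TYPE}> "
                "<http://www.w3.org/1999/02/22-rdf-syntax-ns#Property> .\n"
                f"<{uri}> <{_OWL}deprecated> "
                '"true"^^<http://www.w3.org/2001/XMLSchema#boolean> .'
            )
        else:
            body = f"<{uri}> <{_RDF_TYPE}> <{_OWL}DeprecatedProperty> ."
        fixture[uri] = _turtle(body)
    fixture[predicate] = _turtle(_definition_body(predicate))
    for uri in fillers:
        fixture[uri] = _turtle(_definition_body(uri))
    return fixture


def _build_ledger(spec, injected, witness, document) -> ForgeLedger:
    inventory = extract_components(document)
    assert inventory.n_uris == spec.n_uris
    assert inventory.n_literals == spec.n_literals
    assert inventory.n_blank_nodes == spec.n_blank_nodes

    n_classes = spec.misplaced_class + spec.deprecated_class
    n_properties = (
        spec.misplaced_property + spec.misused_datatype
        + spec.misused_object + spec.deprecated_property
    )
    error_sets = {
        "non_resolvable_uris": injected["non_resolvable"],
        "non_parsable_uris": injected["non_parsable"],
        "undefined_uris": injected["undefined"],
        "misplaced_classes_or_properties": (
            injected["misplaced_class"] + injected["misplaced_property"]
        ),
        "misused_datatype_or_object_property": (
            injected["misused_datatype"] + injected["misused_object"]
        ),
        "deprecated_classes_or_properties": (
            injected["deprecated_class"] + injected["deprecated_property"]
        ),
    }
    denominators = {
        "non_resolvable_uris": spec.n_uris,
        "non_parsable_uris": spec.n_uris,
        "undefined_uris": spec.n_uris,
        "misplaced_classes_or_properties": n_classes + n_properties,
        "misused_datatype_or_object_property": n_properties,
        "deprecated_classes_or_properties": n_classes + n_properties,
    }
    expected = {}
    for metric_id, uris in error_sets.items():
        errors = set(uris)
        affected = sum(
            1
            for triple in document.triples()
            if any(isinstance(t, URIRef) and str(t) in errors for t in triple)
        )
        ordered = tuple(sorted(errors))
        expected[metric_id] = ExpectedMetric(
            error_uris=ordered,
            numerator=len(ordered),
            denominator=denominators[metric_id],
            affected_triples=affected,
            total_triples=inventory.n_triples,
        )
    witness_nt = {
        category: tuple(
            " ".join(term.n3() for term in triple) + " ."
            for triple in triples
        )
        for category, triples in witness.items()
    }
    return ForgeLedger(
        injected={c: injected[c] for c in CATEGORIES},
        witness_triples=witness_nt,
        inventory=inventory,
        expected_metrics=expected,
    )


def random_spec(seed: int, max_uris: int = 2000,
                max_injections_per_category: int = 5) -> ForgeSpec:
    """Draw a feasible random :class:`ForgeSpec` from a seed.

    Each category receives 0 to ``max_injections_per_category``
    injections; the URI total is drawn between the feasibility minimum
    and ``max_uris``.  Used to sample assessment conditions for
    randomized pipeline checks.
    """
    rng = random.Random(seed)
    counts = {c: rng.randint(0, max_injections_per_category) for c in CATEGORIES}
    total = sum(counts.values())
    n_uris = rng.randint(total + 2, max(total + 2, max_uris))
    return ForgeSpec(
        seed=seed,
        n_uris=n_uris,
        n_literals=counts["misused_object"] + rng.randint(0, 20),
        n_blank_nodes=rng.randint(0, 8),
        **counts,
    )


def write_forge_outputs(result: ForgeResult, out_dir: str) -> dict[str, str]:
    """Write resource.ttl, fixtures.json, and ledger.json to a directory."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "resource": os.path.join(out_dir, "resource.ttl"),
        "fixtures": os.path.join(out_dir, "fixtures.json"),
        "ledger": os.path.join(out_dir, "ledger.json"),
    }
    result.document.graph.serialize(paths["resource"], format="turtle")
    with open(paths["fixtures"], "w", encoding="utf-8") as fh:
        json.dump(result.fixture_map, fh, indent=1, sort_keys=True)
    with open(paths["ledger"], "w", encoding="utf-8") as fh:
        json.dump(result.ledger.to_json_dict(), fh, indent=1, sort_keys=True)
    return paths
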