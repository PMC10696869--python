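"""Parsing of RDF documents and extraction of their basic components.

The assessment workflow operates on the components of an RDF graph:
the set of unique URIs (by exact string identity), and the counts of
literal occurrences, blank nodes, and triples.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional
from urllib.parse import urlparse

from rdflib import BNode, Graph, Literal, URIRef

#: Canonical rdflib parser name for every serialization the tool accepts.
FORMAT_ALIASES: dict[str, str] = {
    "turtle": "turtle",
    "ttl": "turtle",
    "rdfxml": "xml",
    "rdf/xml": "xml",
    "xml": "xml",
    "ntriples": "nt",
    "n-triples": "nt",
    "nt": "nt",
    "jsonld": "json-ld",
    "json-ld": "json-ld",
    "n3": "n3",
    "notation3": "n3",
}

#: File-extension based auto-detection (first stage; a hint always wins).
FORMAT_BY_EXTENSION: dict[str, str] = {
    ".ttl": "turtle",
    ".turtle": "turtle",
    ".rdf": "xml",
    ".owl": "xml",
    ".xml": "xml",
    ".nt": "nt",
    ".jsonld": "json-ld",
    ".json": "json-ld",
    ".n3": "n3",
}

#: Sniffing order when neither hint nor extension decides.
SNIFF_ORDER = ("turtle", "xml", "nt", "json-ld", "n3")


class DocumentLoadError(Exception):
    """A document could not be read or parsed.

    ``serialization`` names the format (or formats) that were attempted,
    so callers can distinguish an unknown hint from unparsable content.
    """

    def __init__(self, message: str, serialization: Optional[str] = None):
        super().__init__(message)
        self.serialization = serialization


@dataclass
class SourceDocument:
    """A parsed RDF document under assessment."""

    identifier: str
    serialization: str
    graph: Graph = field(repr=False)

    def triples(self) -> Iterator[tuple]:
        return iter(self.graph)

    def __len__(self) -> int:
        return len(self.graph)


@dataclass(frozen=True)
class ComponentInventory:
    """Component counts of a document: the denominator side of the metrics.

    ``unique_uris`` holds every URI occurring in any triple position,
    deduplicated by exact string equality — two URIs differing only in a
    ``#fragment`` are distinct entries.  ``n_literals`` counts literal
    occurrences (one per object slot), ``n_blank_nodes`` counts distinct
    blank nodes.
    """

    unique_uris: frozenset[str]
    n_literals: int
    n_blank_nodes: int
    n_triples: int

    @property
    def n_uris(self) -> int:
        return len(self.unique_uris)


def _detect_format(locator: str, data: Optional[bytes] = None) -> Optional[str]:
    path = urlparse(locator).path if "://" in locator else locator
    ext = os.path.splitext(path)[1].lower()
    return FORMAT_BY_EXTENSION.get(ext)


def load_document(
    path_or_url: str, serialization_hint: Optional[str] = None
) -> SourceDocument:
    """Load and parse an RDF document from a file path or URL.

    Serialization is resolved in order: explicit ``serialization_hint``,
    file extension, then content sniffing (each candidate parser tried in
    :data:`SNIFF_ORDER`).  Parse failure raises :class:`DocumentLoadError`
    naming the serialization(s) tried.
    """
    if serialization_hint is not None:
        fmt = FORMAT_ALIASES.get(serialization_hint.lower())
        if fmt is None:
            raise DocumentLoadError(
                f"unknown serialization hint {serialization_hint!r}",
                serialization=serialization_hint,
            )
        candidates = [fmt]
    else:
        fmt = _detect_format(path_or_url)
        candidates = [fmt] if fmt else list(SNIFF_ORDER)

    last_error: Optional[Exception] = None
    for candidate in candidates:
        graph = Graph()
        try:
            graph.parse(path_or_url, format=candidate)
        except FileNotFoundError:
            raise DocumentLoadError(f"cannot read {path_or_url!r}: not found")
        except Exception as exc:  # rdflib raises many parser-specific types
            last_error = exc
            continue
        return SourceDocument(
            identifier=path_or_url, serialization=candidate, graph=graph
        )
    raise DocumentLoadError(
        f"content of {path_or_url!r} is not parsable as any of "
        f"{candidates} ({last_error})",
        serialization=",".join(candidates),
    )


def document_from_graph(graph: Graph, identifier: str = "urn:rdfqa:in-memory",
                        serialization: str = "turtle") -> SourceDocument:
    """Wrap an already-built rdflib graph as a :class:`SourceDocument`."""
    return SourceDocument(identifier=identifier, serialization=serialization,
                          graph=graph)


def extract_components(doc: SourceDocument) -> ComponentInventory:
    """One-pass scan collecting unique URIs and term counts."""
    uris: set[str] = set()
    bnodes: set[str] = set()
    n_literals = 0
    n_triples = 0
    for s, p, o in doc.triples():
        n_triples += 1
        for term in (s, p, o):
            if isinstance(term, URIRef):
                uris.add(str(term))
            elif isinstance(term, BNode):
                bnodes.add(str(term))
            elif isinstance(term, Literal):
                n_literals += 1
    return ComponentInventory(
        unique_uris=frozenset(uris),
        n_literals=n_literals,
        n_blank_nodes=len(bnodes),
        n_triples=n_triples,
    )
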