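"""Parsability and definedness of dereferenced URIs.

After resolution, a URI with an RDF content type is parsed with the
parser its media type maps to.  A response that does not contain at
least one triple is non-parsable.  A URI that parses is *defined* iff
the exact URI string occurs in any position of at least one retrieved
triple — matching is purely syntactic, so hash and hashless variants of
the same document URI are different terms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from rdflib import Graph, URIRef

from .inventory import ComponentInventory
from .resolution import (
    RDF_MEDIA_TYPES,
    ResolutionOutcome,
    TransportContract,
    classify_resolvability,
    strip_fragment,
)


class Stage(str, enum.Enum):
    """Terminal classification of one URI in the assessment cascade."""

    NON_RESOLVABLE = "non_resolvable"
    NON_RDF_CONTENT = "non_rdf_content"
    NON_PARSABLE = "non_parsable"
    UNDEFINED = "undefined"
    DEFINED = "defined"


#: Stages that count as errors. Serving non-RDF content is *not* an
#: error: such a URI simply advertises that it has no RDF representation.
ERROR_STAGES = frozenset(
    {Stage.NON_RESOLVABLE, Stage.NON_PARSABLE, Stage.UNDEFINED}
)


@dataclass
class UriVerdict:
    uri: str
    stage: Stage
    retrieved_graph: Optional[Graph] = field(default=None, repr=False)
    detail: str = ""
    status_code: int = 0
    content_type: Optional[str] = None


def parse_retrieved_content(outcome: ResolutionOutcome) -> Optional[Graph]:
    """Parse the body of an RDF-content-type response.

    The parser is chosen from the declared media type; there is no
    format sniffing on mismatch, because the non-parsable metric is
    about the *declared* representation.  Returns ``None`` when the body
    fails to parse or parses to an empty graph (zero triples is "does
    not contain at least one RDF graph").
    """
    fmt = RDF_MEDIA_TYPES.get(outcome.content_type or "")
    if fmt is None:
        raise ValueError(
            f"{outcome.uri}: content type {outcome.content_type!r} is not RDF"
        )
    graph = Graph()
    try:
        graph.parse(data=outcome.body, format=fmt)
    except Exception:
        return None
    if len(graph) == 0:
        return None
    return graph


def _graph_uri_strings(graph: Graph) -> set[str]:
    terms: set[str] = set()
    for triple in graph:
        for term in triple:
            if isinstance(term, URIRef):
                terms.add(str(term))
    return terms


def check_defined(
    uri: str, retrieved_graph: Graph, subject_only: bool = False
) -> bool:
    """Does the retrieved graph specify the URI?

    Default mode: the exact URI string occurs in *any* triple position.
    ``subject_only`` restricts the match to the subject slot (a stricter
    reading, provided for comparison).
    """
    ref = URIRef(uri)
    if subject_only:
        return next(retrieved_graph.triples((ref, None, None)), None) is not None
    return str(uri) in _graph_uri_strings(retrieved_graph)


def cascade_verdicts(
    inventory: ComponentInventory,
    transport: TransportContract,
    subject_only: bool = False,
) -> dict[str, UriVerdict]:
    """Run the full per-URI cascade: resolve → content-type → parse → defined.

    Every unique URI lands in exactly one of the five stages.  Hash URIs
    sharing a document reuse one fetched, parsed graph keyed by the
    defragmented request URI.
    """
    outcomes = classify_resolvability(inventory, transport)
    # Parse once per retrieved document, not once per hash URI.
    parsed_cache: dict[str, Optional[Graph]] = {}
    verdicts: dict[str, UriVerdict] = {}
    for uri, outcome in outcomes.items():
        common = dict(status_code=outcome.status_code,
                      content_type=outcome.content_type)
        if not outcome.resolvable:
            verdicts[uri] = UriVerdict(
                uri, Stage.NON_RESOLVABLE,
                detail=outcome.reason or f"HTTP status {outcome.status_code}",
                **common)
            continue
        if not outcome.is_rdf_content:
            verdicts[uri] = UriVerdict(
                uri, Stage.NON_RDF_CONTENT,
                detail=f"content type {outcome.content_type!r} is not an RDF "
                       "media type; not further analyzed (not an error)",
                **common)
            continue
        key = strip_fragment(uri)
        if key not in parsed_cache:
            parsed_cache[key] = parse_retrieved_content(outcome)
        graph = parsed_cache[key]
        if graph is None:
            verdicts[uri] = UriVerdict(
                uri, Stage.NON_PARSABLE,
                detail=f"content declared {outcome.content_type!r} but did not "
                       "yield at least one triple",
                **common)
            continue
        if check_defined(uri, graph, subject_only=subject_only):
            verdicts[uri] = UriVerdict(uri, Stage.DEFINED,
                                       retrieved_graph=graph, **common)
        else:
            verdicts[uri] = UriVerdict(
                uri, Stage.UNDEFINED, retrieved_graph=graph,
                detail="URI does not occur in the triples retrieved by "
                       "resolving it (exact string match)",
                **common)
    return verdicts


def verdicts_to_rows(verdicts: dict[str, UriVerdict]) -> list[dict]:
    """Flatten verdicts for CSV export: uri, stage, status, content type."""
    return [
        {
            "uri": v.uri,
            "stage": v.stage.value,
            "status_code": v.status_code,
            "content_type": v.content_type or "",
            "detail": v.detail,
        }
        for v in verdicts.values()
    ]
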