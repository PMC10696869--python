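"""End-to-end assessment orchestration.

``assess_document`` runs the whole workflow on a parsed document:
component extraction, URI resolution, the parsability/definedness
cascade, term typing and consistency checks, and finally the six metric
results — returning everything in one :class:`Assessment` bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

from rdflib import Graph, URIRef

from .consistency import (
    DEFAULT_DEFINING_PREDICATES,
    OWL_PROPERTY_TYPES,
    ConsistencyError,
    TermTyping,
    find_all_consistency_errors,
    type_terms,
)
from .definitions import UriVerdict, cascade_verdicts
from .inventory import ComponentInventory, SourceDocument, extract_components
from .metrics import MetricResult, compute_metric_results, format_cell
from .reporting import build_report
from .resolution import TransportContract


@dataclass
class AssessmentConfig:
    """Knobs for the consistency stage and the definedness rule."""

    defining_predicates: frozenset[URIRef] = DEFAULT_DEFINING_PREDICATES
    owl_property_types: frozenset[URIRef] = OWL_PROPERTY_TYPES
    subject_only_definition_mode: bool = False


@dataclass
class Assessment:
    document: SourceDocument
    inventory: ComponentInventory
    verdicts: dict[str, UriVerdict] = field(repr=False)
    typings: dict[str, TermTyping] = field(repr=False)
    consistency_errors: list[ConsistencyError] = field(repr=False)
    results: list[MetricResult]

    def report(
        self,
        resource_id: Optional[str] = None,
        generated_at: Optional[datetime] = None,
        failures_only: bool = False,
    ) -> Graph:
        return build_report(
            resource_id or self.document.identifier,
            self.results,
            generated_at=generated_at,
            failures_only=failures_only,
        )

    def summary_lines(self) -> list[str]:
        """Per-metric lines: errors/denominator and affected triples."""
        lines = []
        for r in self.results:
            lines.append(
                f"{r.metric_id}: {format_cell(r.numerator, r.denominator)}"
                f"  affected triples: "
                f"{format_cell(r.affected_triples, r.total_triples)}"
            )
        return lines


def assess_document(
    doc: SourceDocument,
    transport: TransportContract,
    config: Optional[AssessmentConfig] = None,
) -> Assessment:
    """Run the full quality-assessment workflow on one document."""
    if config is None:
        config = AssessmentConfig()
    inventory = extract_components(doc)
    verdicts = cascade_verdicts(
        inventory, transport,
        subject_only=config.subject_only_definition_mode,
    )
    typings = type_terms(verdicts, config.owl_property_types)
    errors = find_all_consistency_errors(
        doc, typings, config.defining_predicates
    )
    results = compute_metric_results(verdicts, errors, typings, inventory, doc)
    return Assessment(
        document=doc,
        inventory=inventory,
        verdicts=verdicts,
        typings=typings,
        consistency_errors=errors,
        results=results,
    )
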