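"""The six quality metric results.

Each metric reports an ordered set of erroneous URIs, a
numerator/denominator pair, and the number of document triples affected
(triples containing at least one erroneous URI of that metric).

Denominators:

* non-resolvable / non-parsable / undefined URIs — all unique URIs;
* misplaced classes or properties — unique classes plus unique
  properties among the document's defined URIs;
* misused DatatypeProperty/ObjectProperty — all unique properties;
* deprecated classes or properties — unique classes plus properties.

Percentages are formatted to one decimal (round-half-up) as a
presentation concern only; comparisons use exact rationals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from rdflib import URIRef

from .consistency import ConsistencyError, ErrorKind, TermTyping
from .definitions import Stage, UriVerdict
from .inventory import ComponentInventory, SourceDocument

#: Canonical metric order, used everywhere a report enumerates metrics.
METRIC_IDS: tuple[str, ...] = (
    "non_resolvable_uris",
    "non_parsable_uris",
    "undefined_uris",
    "misplaced_classes_or_properties",
    "misused_datatype_or_object_property",
    "deprecated_classes_or_properties",
)

_STAGE_METRICS = {
    "non_resolvable_uris": Stage.NON_RESOLVABLE,
    "non_parsable_uris": Stage.NON_PARSABLE,
    "undefined_uris": Stage.UNDEFINED,
}

_KIND_METRICS = {
    "misplaced_classes_or_properties": (
        ErrorKind.MISPLACED_CLASS,
        ErrorKind.MISPLACED_PROPERTY,
    ),
    "misused_datatype_or_object_property": (
        ErrorKind.MISUSED_DATATYPE_PROPERTY,
        ErrorKind.MISUSED_OBJECT_PROPERTY,
    ),
    "deprecated_classes_or_properties": (
        ErrorKind.DEPRECATED_CLASS,
        ErrorKind.DEPRECATED_PROPERTY,
    ),
}


@dataclass(frozen=True)
class MetricResult:
    metric_id: str
    error_uris: tuple[str, ...]
    denominator: int
    affected_triples: int
    total_triples: int

    @property
    def numerator(self) -> int:
        return len(self.error_uris)

    @property
    def proportion(self) -> Fraction:
        if self.denominator == 0:
            return Fraction(0)
        return Fraction(self.numerator, self.denominator)

    @property
    def value(self) -> str:
        """The measurement value as printed in reports, e.g. ``"6/54"``."""
        return f"{self.numerator}/{self.denominator}"


def round_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded half-up at ``decimals`` places; 0/0 is 0."""
    if denominator == 0:
        return 0.0
    pct = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def format_cell(numerator: int, denominator: int) -> str:
    """Tabular cell like ``6/54 (11.1%)`` with thousands separators."""
    pct = round_percent(numerator, denominator)
    return f"{numerator:,}/{denominator:,} ({pct:.1f}%)"


def count_affected_triples(doc: SourceDocument, error_uris: Iterable[str]) -> int:
    """Triples of the document containing >= 1 erroneous URI in any slot."""
    errors = set(error_uris)
    if not errors:
        return 0
    n = 0
    for triple in doc.triples():
        if any(isinstance(t, URIRef) and str(t) in errors for t in triple):
            n += 1
    return n


def _class_property_counts(
    typings: Mapping[str, TermTyping]
) -> tuple[int, int]:
    applicable = {u: t for u, t in typings.items() if t.consistency_applicable}
    n_classes = sum(1 for t in applicable.values() if t.is_class)
    n_properties = sum(1 for t in applicable.values() if t.is_property)
    return n_classes, n_properties


def compute_metric_results(
    verdicts: Mapping[str, UriVerdict],
    consistency_errors: Sequence[ConsistencyError],
    typings: Mapping[str, TermTyping],
    inventory: ComponentInventory,
    doc: SourceDocument,
) -> list[MetricResult]:
    """Assemble the six metric results from the upstream stages."""
    n_uris = inventory.n_uris
    n_classes, n_properties = _class_property_counts(typings)
    denominators = {
        "non_resolvable_uris": n_uris,
        "non_parsable_uris": n_uris,
        "undefined_uris": n_uris,
        "misplaced_classes_or_properties": n_classes + n_properties,
        "misused_datatype_or_object_property": n_properties,
        "deprecated_classes_or_properties": n_classes + n_properties,
    }
    results = []
    for metric_id in METRIC_IDS:
        if metric_id in _STAGE_METRICS:
            stage = _STAGE_METRICS[metric_id]
            errors = sorted(
                u for u, v in verdicts.items() if v.stage is stage
            )
        else:
            kinds = _KIND_METRICS[metric_id]
            errors = sorted(
                {e.uri for e in consistency_errors if e.kind in kinds}
            )
        results.append(
            MetricResult(
                metric_id=metric_id,
                error_uris=tuple(errors),
                denominator=denominators[metric_id],
                affected_triples=count_affected_triples(doc, errors),
                total_triples=inventory.n_triples,
            )
        )
    return results
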