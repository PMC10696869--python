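# Methods

## Assessment model

`rdfqa` treats an RDF document as a bag of triples over three term
kinds — URIs, literals, blank nodes — and assesses the *unique URI
set* at the syntactic level. Uniqueness and all matching are exact
string comparison: no case folding, no hash/hashless unification, no
`owl:sameAs` reasoning. This is deliberate: dereferencing is defined
on the URI string, and any pattern-level identification of variants
(e.g. `…/rdf-syntax-ns` vs `…/rdf-syntax-ns#`) would hide exactly the
authoring mistakes the metrics exist to surface. The known cost is
that a handful of ontology-document URIs that humans would call
"defined" are classified undefined; the verdict's `detail` field keeps
the classification auditable.

### The per-URI cascade

Every unique URI receives exactly one of five terminal stages:

1. **non_resolvable** — final HTTP status (after redirects) in
   400–599, or a network failure after retries, or a URI that cannot
   be requested at all (non-http(s) scheme, malformed). The last two
   carry sentinel status 0 and a distinct reason string so they can be
   filtered in reports; they still count as non-resolvable because the
   metric's operational meaning is "dereferencing cannot supply a
   definition". HTTP 423 (a server-side blocking mechanism) likewise
   counts as non-resolvable but remains distinguishable by its status
   code.
2. **non_rdf_content** — resolvable, but the normalized media type
   (lowercased, parameters stripped) is not one of the six negotiated
   RDF types. Not an error: the server is honestly advertising a
   non-RDF representation. The cascade stops here; the URI appears in
   no error list.
3. **non_parsable** — an RDF media type whose body, parsed with the
   parser that media type maps to, raises or yields zero triples. An
   empty-but-valid document is non-parsable (no RDF graph was
   retrieved). There is no format sniffing on mismatch — the metric is
   about the declared representation — and `text/plain` is parsed as
   N-Triples, so prose served as `text/plain` is non-parsable. This is
   harsh but follows directly from the media-type table.
4. **undefined** — parses, but the exact URI string occurs in no
   position of any retrieved triple.
5. **defined** — occurs in at least one retrieved triple, in any
   position. "Any position" is the default because a definition
   document may mention a term as object (e.g. in a range axiom)
   without a subject-position triple; a stricter subject-only mode is
   available (`subject_only_definition_mode`) for comparison.

Fragments are stripped for the HTTP request but verdicts are recorded
per full URI string, so `…ns#a` and `…ns#b` share one fetch and one
parsed graph (cached by defragmented URL) while keeping independent
verdicts. This caching is what makes ontologies with tens of
thousands of hash URIs tractable.

### Typing and consistency

Term typing derives only from a URI's *definition graph* (the triples
its own resolution returned), never from the assessed document — the
assessed document is the thing under test. A term is a class if typed
`owl:Class`, `rdfs:Class`, or `owl:DeprecatedClass` (the latter is a
class type in the OWL vocabulary), and a property if typed
`rdf:Property` or any OWL property type. The OWL property-type set is
configuration-visible (`owl_property_types`) because "any OWL
property" is open-ended; the default covers the eleven OWL 1/2
property classes plus `owl:DeprecatedProperty`.

Consistency rules applied to the assessed document:

* **misplaced class** — a class in the predicate slot;
* **misplaced property** — a property in the object slot, unless the
  triple's predicate is in the *defining predicates* set (default:
  `rdf:type`, `rdfs:subPropertyOf`, `owl:onProperty`,
  `owl:equivalentProperty`, `owl:inverseOf`,
  `owl:propertyDisjointWith`, `rdfs:seeAlso`, `dcterms:relation`;
  overridable, since the notion of a "defining triple" is open-ended);
* **misused flavors** — a `owl:DatatypeProperty` predicate with a URI
  object, or an `owl:ObjectProperty` predicate with a literal object.
  Blank-node objects trigger neither rule (a blank node is neither a
  URI nor a literal). Annotation properties are exempt: OWL imposes
  no range discipline on them. A punned term (class *and* property)
  is evaluated under both rule families.
* **deprecated term in use** — any of four patterns in the definition
  graph: `owl:deprecated "true"^^xsd:boolean` on a class or property,
  or typing by `owl:DeprecatedClass` / `owl:DeprecatedProperty`. The
  literal must be a typed boolean true; untyped `"true"` or boolean
  `"false"` do not deprecate. Deprecated terms remain subject to the
  other consistency rules.

`owl:NamedIndividual`s that are neither classes nor properties are
exempt from all consistency rules; only resolvability and parsability
apply to instances.

Every consistency error carries a witness triple from the assessed
document, so error lists are independently checkable by membership.

### Metrics and denominators

The three URI-level metrics use all unique URIs as denominator. The
consistency metrics use the classes/properties found *among the
document's defined URIs*: misplaced and deprecated over classes +
properties, misuse over properties. (Whether "all unique classes"
should mean classes used by the document or classes defined anywhere
is genuinely ambiguous; the used-by-the-document reading matches the
published per-resource denominators such as 1/19 and 1/88 misused
properties, and is the only one computable without a global registry.)
A zero denominator yields a defined "0/0" result reported as 0%.

Affected-triple counts are a per-metric single scan: a triple is
affected if any of its three terms is in that metric's error set.

Percentages are formatted to one decimal, round-half-up; all internal
comparisons (including the SPARQL `>10%` filter, which computes
`n*10 > N` in exact decimal arithmetic on the `"n/N"` value string)
use exact rationals, never the rounded presentation string.

## DQV reports and queries

A report graph types the assessed resource `dcat:Resource` and links
one `dqv:QualityMeasurement` per metric via
`dqv:hasQualityMeasurement`; each measurement carries
`dqv:isMeasurementOf` (a metric URI in the `http://purl.org/fqm#`
namespace), `dqv:value` with the lexical fraction (`"6/54"`),
`prov:generatedAtTime` (ISO-8601), and one `dcterms:relation` link per
erroneous URI. Passing metrics get `"0/N"` measurements by default so
"which metrics were tested" stays queryable; `failures_only` mode
emits only failing measurements. Measurement node URIs are minted
deterministically (a hash of resource × metric), so identical inputs
give isomorphic reports. Only two of the six metric URIs are fixed by
the FQM vocabulary; the other four follow the same naming style and
sit behind a remappable table (`DEFAULT_METRIC_URIS`).

The three bundled SPARQL questions are plain SPARQL 1.1 SELECT over
any store holding report graphs; question 3 joins measurements to
`skos:definition` strings shipped in a small metric-definitions graph.

## The fixture forge

The forge emulates the study conditions the pipeline is meant to
operate under: desk-scale biomedical RDF documents (tens to a few
thousand unique URIs) in which each error category occurs a known
number of times. A `ForgeSpec` fixes seed, URI/literal/blank-node
counts, an optional exact triple total, and per-category injection
counts; generation is a pure function of the spec. Injections occupy
the leading URI indices (deterministic-first) so ledgers are stable
under edits; the seeded stream drives URI naming and filler placement.
Each injection realizes its defining condition literally: 4xx/5xx
statuses for non-resolvable; RDF media types over garbage or empty
bodies for non-parsable; a parsable graph omitting the URI for
undefined; definition graphs declaring flavor plus a violating
document triple for misuse; the exact deprecation triple patterns for
deprecated terms. Filler triples draw their predicate from a single
reserved, untyped URI so they can never create accidental classes,
properties, or rule matches. All URIs live under
`http://fixture.invalid/`, a non-registrable base, and strict offline
mode refuses anything outside the fixture map.

The ledger (category sets, witness triples, inventory, six expected
metric results with affected-triple counts, computed from construction
knowledge plus an independent scan of the emitted triple list) is the
oracle the assessor is tested against.

What the forge does *not* emulate: realistic ontology topology (class
hierarchies, axiom patterns, annotation density), shared definition
documents for many hash URIs at scale, redirect chains, or content
negotiation where a server's response depends on the Accept header.
Passing the forge-based suite therefore demonstrates the correctness
of the classification and counting machinery under controlled
conditions, not robustness to the full messiness of live web servers —
live-mode behavior (retries, backoff, redirects) is exercised only
lightly.

## The published-summary replay

A sixteen-resource rare-disease assessment published on 2022-12-30 is
transcribed (numerators, denominators, affected-triple pairs,
percentages as printed) as input data in `published_summary.py`. Its
error counts depend on web state at that date and cannot be reproduced
by re-fetching; the replay instead rebuilds DQV reports from the
printed pairs — with synthetic placeholder URIs standing in for the
unrecorded error URIs — so the SPARQL questions can be checked against
the published aggregate answers (5 resources over 10% non-resolvable
with the blocked special-case resource excluded per its footnote; 69
undefined-URI rows; 3 failed metrics for the WikiPathways ontology
row). Seven transcribed cells are kept verbatim although their
printed percentage is not the round-half-up value of their printed
fraction (six look truncated instead of rounded; one undefined-URI
cell mixes two denominators); they are listed in
`FORMATTING_ANOMALIES` and the formatting tests assert both that all
other cells agree and that exactly these do not.

## Numerical and design choices

* **Status classes**: 1xx/2xx/3xx-resolved are resolvable; only
  4xx/5xx (or no response at all) are not.
* **Retry policy** (live transport only): 3 attempts, exponential
  backoff ×1 s, retrying 5xx/429/timeouts, never 4xx; 30 s timeout;
  GET rather than HEAD because the body is needed downstream. All
  configurable.
* **Accept header**: the six RDF media types at implicit q=1.0,
  `*/*;q=0.1` last.
* **Literal counting**: literal occurrences (one per object slot),
  not deduplicated lexical forms; blank nodes are counted as distinct
  nodes and never enter any metric denominator.
* **Serialization detection**: explicit hint wins, then file
  extension, then parser sniffing in a fixed order.
* **Problem sizes**: the randomized suites use fifty forged resources
  of up to 2,000 URIs for exact ledger recovery and a thousand small
  resources (≤ 25 URIs) for the cascade-partition property — sizes
  chosen to exercise caching and padding logic thoroughly while
  keeping the whole suite fast enough to run on every change.

## Known limitations

* Syntactic-only matching (above) — no semantic identity.
* No named-graph/quad input (TriG, N-Quads) and no streaming parse;
  documents are assumed to fit in memory.
* No full OWL reasoning: logical inconsistency (disjointness
  violations, unsatisfiable classes) and instance-level checks beyond
  the NamedIndividual exemption are out of scope.
* Sequential fetching; no robots.txt handling or authentication.
* DOI-style identifiers are assessed by the standard cascade like any
  other URI, which classifies them undefined when the landing
  metadata does not mention the DOI URI itself.
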