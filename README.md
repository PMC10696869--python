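# rdfqa

Foundational quality assessment of RDF resources — biomedical
ontologies, vocabularies, schemas, and metadatasets — with
machine-readable assessment reports.

Linked-data resources in domains such as rare disease research
(ontologies like ORDO, HPO, GO; registry and biobank metadatasets)
routinely reference URIs that no longer resolve, resolve to content
that is not parsable RDF, are never defined by the documents they
resolve to, or use classes and properties inconsistently with their
declared semantics. `rdfqa` measures six objective, automatable
quality metrics over any RDF document and publishes the result as a
W3C Data Quality Vocabulary (DQV) report that can be queried with
SPARQL.

## The six metrics

For an assessed document with unique URI set *U* (exact string
identity — `…/ns` and `…/ns#` are distinct):

| metric | numerator | denominator |
|---|---|---|
| non-resolvable URIs | URIs whose final HTTP status is 4xx/5xx | \|U\| |
| non-parsable URIs | URIs served with an RDF media type whose body yields no triple | \|U\| |
| undefined URIs | URIs absent from the triples retrieved by resolving them | \|U\| |
| misplaced classes or properties | classes used as predicates; properties used as objects of non-defining triples | classes + properties |
| misused owl:DatatypeProperty / owl:ObjectProperty | datatype properties with URI objects; object properties with literal objects | properties |
| deprecated classes or properties | terms marked `owl:deprecated "true"^^xsd:boolean` or typed `owl:DeprecatedClass` / `owl:DeprecatedProperty` | classes + properties |

Each unique URI is dereferenced once (fragments stripped for the
request, RDF-preferring content negotiation via a weighted `Accept`
header) and classified through a five-stage cascade: *non-resolvable →
non-RDF content → non-parsable → undefined → defined*. Serving
non-RDF content is **not** an error — such a URI merely announces that
it has no RDF representation. Classes and properties are typed from
their own definition graphs; `owl:NamedIndividual`s are assessed only
for resolvability and parsability. Every metric also reports the
number of *affected triples* — document triples containing at least
one erroneous URI.

Because live web state drifts, the whole pipeline runs offline against
a *fixture map* (URI → canned HTTP response). The built-in fixture
forge generates synthetic resources with exact, ledgered error counts
in every category, so expected outputs are known in advance.

## Worked example

Forge a resource shaped like a small patient-registry metadataset —
54 unique URIs, 10 literals, 47 triples, six injected non-resolvable
URIs — then assess it against its own fixture map:

```bash
cat > /tmp/spec.json <<'EOF'
{"seed": 1, "n_uris": 54, "non_resolvable": 6,
 "n_literals": 10, "n_triples": 47}
EOF
rdfqa forge --spec /tmp/spec.json --out-dir /tmp/forged
rdfqa assess --input /tmp/forged/resource.ttl \
             --offline-map /tmp/forged/fixtures.json --strict-offline \
             --output /tmp/report.ttl --failures-only
```

prints

```
non_resolvable_uris: 6/54 (11.1%)  affected triples: 6/47 (12.8%)
non_parsable_uris: 0/54 (0.0%)  affected triples: 0/47 (0.0%)
undefined_uris: 0/54 (0.0%)  affected triples: 0/47 (0.0%)
misplaced_classes_or_properties: 0/0 (0.0%)  affected triples: 0/47 (0.0%)
misused_datatype_or_object_property: 0/0 (0.0%)  affected triples: 0/47 (0.0%)
deprecated_classes_or_properties: 0/0 (0.0%)  affected triples: 0/47 (0.0%)
report written to /tmp/report.ttl
```

Six of the 54 unique URIs (11.1%) fail to resolve, touching 6 of the
47 triples; no other metric fires, and the consistency metrics have
denominator 0 because the fixture defines no classes or properties.
The Turtle report contains one `dqv:QualityMeasurement` with
`dqv:value "6/54"` and six `dcterms:relation` links naming the failing
URIs.

The three bundled quality questions run over any set of reports:

```bash
rdfqa replay-summary --out-dir /tmp/reports --exclude-special-cases
rdfqa query --question 1 --reports /tmp/reports/*.ttl   # > 10% non-resolvable
rdfqa query --question 2 --reports /tmp/reports/*.ttl   # undefined URIs
```

(`replay-summary` rebuilds DQV reports from a published sixteen-resource
rare-disease assessment shipped as input data; question 1 returns 5
resources, question 2 returns 69 resource/URI pairs.)

Python API:

```python
from rdfqa import ForgeSpec, forge_resource, OfflineTransport, assess_document

result = forge_resource(ForgeSpec(seed=1, n_uris=54, non_resolvable=6,
                                  n_literals=10, n_triples=47))
assessment = assess_document(result.document,
                             OfflineTransport(result.fixture_map, strict=True))
print(assessment.results[0].value)   # "6/54"
```

Live assessment (`rdfqa assess --input https://…`) uses the same
cascade over real HTTP with retry/backoff; it is an optional mode and
never required by the test suite.

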