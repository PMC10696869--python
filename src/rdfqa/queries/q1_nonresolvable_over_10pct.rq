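# Which resources have more than 10% non-resolvable URIs?
# The dqv:value fraction "n/N" is compared exactly: n * 10 > N.
PREFIX dqv: <http://www.w3.org/ns/dqv#>
PREFIX fqm: <http://purl.org/fqm#>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>

SELECT ?resource ?value
WHERE {
  ?resource dqv:hasQualityMeasurement ?measurement .
  ?measurement dqv:isMeasurementOf fqm:uriNonResolvableMetric ;
               dqv:value ?value .
  FILTER (xsd:decimal(STRBEFORE(?value, "/")) * 10 > xsd:decimal(STRAFTER(?value, "/")))
}
ORDER BY ?resource
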