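# Which resources use undefined URIs, and which URIs are they?
PREFIX dqv: <http://www.w3.org/ns/dqv#>
PREFIX fqm: <http://purl.org/fqm#>
PREFIX dcterms: <http://purl.org/dc/terms/>

SELECT ?resource ?undefinedUri
WHERE {
  ?resource dqv:hasQualityMeasurement ?measurement .
  ?measurement dqv:isMeasurementOf fqm:uriUndefinedMetric ;
               dcterms:relation ?undefinedUri .
}
ORDER BY ?resource ?undefinedUri
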