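# What quality issues does a resource have, against which metrics,
# and how are those metrics defined?  ?resource may be pre-bound.
PREFIX dqv: <http://www.w3.org/ns/dqv#>
PREFIX skos: <http://www.w3.org/2004/02/skos/core#>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>

SELECT ?metric ?definition
WHERE {
  ?resource dqv:hasQualityMeasurement ?measurement .
  ?measurement dqv:isMeasurementOf ?metric ;
               dqv:value ?value .
  ?metric skos:definition ?definition .
  FILTER (xsd:integer(STRBEFORE(?value, "/")) > 0)
}
ORDER BY ?metric
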