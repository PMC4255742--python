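# Each study factor with its associated discrete levels.
PREFIX isa: <http://purl.org/isaterms/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?study ?factor ?level
WHERE {
  ?s isa:identifier ?study ;
     isa:hasFactor ?f .
  ?f rdfs:label ?factor ;
     isa:hasLevel ?l .
  ?l rdfs:label ?level .
}
ORDER BY ?study ?factor ?level
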