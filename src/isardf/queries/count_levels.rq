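# Number of distinct levels per study factor.
PREFIX isa: <http://purl.org/isaterms/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?study ?factor (COUNT(DISTINCT ?l) AS ?n_levels)
WHERE {
  ?s isa:identifier ?study ;
     isa:hasFactor ?f .
  ?f rdfs:label ?factor ;
     isa:hasLevel ?l .
}
GROUP BY ?study ?factor
ORDER BY ?study ?factor
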