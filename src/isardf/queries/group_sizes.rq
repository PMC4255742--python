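# Study groups with their defining factor levels and sizes
# (one row per group-level pair; combinations are assembled client-side).
PREFIX isa: <http://purl.org/isaterms/>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
SELECT ?study ?group ?factor ?level ?size
WHERE {
  ?s isa:identifier ?study ;
     isa:hasGroup ?group .
  ?group isa:hasSize ?size ;
         isa:hasLevel ?l .
  ?f isa:hasLevel ?l ;
     rdfs:label ?factor .
  ?s isa:hasFactor ?f .
  ?l rdfs:label ?level .
}
ORDER BY ?study ?group ?factor ?level
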