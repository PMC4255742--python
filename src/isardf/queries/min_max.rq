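# Minimum and maximum study-group size per study.
PREFIX isa: <http://purl.org/isaterms/>
SELECT ?study (MIN(?size) AS ?min_size) (MAX(?size) AS ?max_size)
WHERE {
  ?s isa:identifier ?study ;
     isa:hasGroup ?g .
  ?g isa:hasSize ?size .
}
GROUP BY ?study
ORDER BY ?study
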