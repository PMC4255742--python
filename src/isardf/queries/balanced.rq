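# Is the study design balanced? True when the minimum group size equals
# the maximum group size.
PREFIX isa: <http://purl.org/isaterms/>
SELECT ?study (MIN(?size) = MAX(?size) AS ?balanced)
WHERE {
  ?s isa:identifier ?study ;
     isa:hasGroup ?g .
  ?g isa:hasSize ?size .
}
GROUP BY ?study
ORDER BY ?study
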