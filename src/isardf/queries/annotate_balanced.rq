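# Materialise the balanced-design annotation: type the design individual
# of every study whose minimum and maximum group sizes coincide with the
# balanced-design class (bound externally as ?balancedClass).
PREFIX isa: <http://purl.org/isaterms/>
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
CONSTRUCT { ?d rdf:type ?balancedClass }
WHERE {
  {
    SELECT ?s (MIN(?size) AS ?min_size) (MAX(?size) AS ?max_size)
    WHERE {
      ?s isa:hasGroup ?g .
      ?g isa:hasSize ?size .
    }
    GROUP BY ?s
  }
  FILTER(?min_size = ?max_size)
  ?s isa:hasDesign ?d .
}
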