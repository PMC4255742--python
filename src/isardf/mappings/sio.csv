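# SIO framework mapping: generic attribute/part properties from the
# SemanticScience Integrated Ontology. Types not listed here fall back to
# the ISA vocabulary namespace.
has part,has part,http://purl.obolibrary.org/obo/SIO_000028
has characteristic,has attribute,http://purl.obolibrary.org/obo/SIO_000008
has parameter value,has attribute,http://purl.obolibrary.org/obo/SIO_000008
has unit,has unit,http://purl.obolibrary.org/obo/SIO_000221
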