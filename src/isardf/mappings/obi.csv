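# OBI framework mapping: ISA elements to Ontology for Biomedical
# Investigations classes (plus the STATO balanced-design class used by the
# design-annotation step). Context-dependent rows carry a parenthesised
# context: a Protocol REF in a study table is a material processing, in an
# assay table the more generic planned process.
Investigation,investigation,http://purl.obolibrary.org/obo/OBI_0000066
Study Assay,assay,http://purl.obolibrary.org/obo/OBI_0000070
Protocol REF (study),material processing,http://purl.obolibrary.org/obo/OBI_0000094
Protocol REF (assay),planned process,http://purl.obolibrary.org/obo/OBI_0000011
Characteristics[OBI:organism],organism,http://purl.obolibrary.org/obo/OBI_0100026
Sample Name,specimen,http://purl.obolibrary.org/obo/OBI_0100051
balanced design,balanced design,http://purl.obolibrary.org/obo/STATO_0000003
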