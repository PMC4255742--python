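# isardf — ISA-Tab experimental metadata to RDF

`isardf` converts ISA-Tab archives — the tab-delimited
Investigation/Study/Assay format used to describe biological experiments —
into RDF, and then lets you interrogate the experimental *design* with a
small SPARQL query suite.

ISA-Tab stores an experiment as spreadsheet-like tables whose rows are
paths through a directed acyclic graph: material nodes (`Source Name`,
`Sample Name`, `Extract Name`, …) and data nodes (`Raw Data File`, …)
alternate with `Protocol REF` columns, each row-level protocol reference
being one process application with the node to its left as input and the
node to its right as output. The format is convenient for humans but its
semantics are implicit. `isardf` makes them explicit:

- **Graph recovery.** Tables are segmented into a DAG using ISA identity
  rules: materials and data files are identified by *(kind, name)* — so a
  sample shared by the study and an assay table is one node — while a
  process is identified by the tuple *(protocol, parameter values, inputs,
  outputs)*, so two rows naming the same protocol may be one application or
  two. Processes are classified as material→material, material→data or
  data→data.
- **Pluggable semantics.** Delimited mapping files bind ISA syntactic
  elements to ontology classes and properties. Packaged defaults cover an
  ISA base vocabulary plus OBI, SIO and PROV-O flavours — e.g. under OBI a
  `Protocol REF` in a study table is *material processing*
  (`OBI_0000094`) but in an assay table the more generic *planned process*
  (`OBI_0000011`), and a `Characteristics[OBI:organism]` column is the
  *organism* category (`OBI_0100026`) whose annotated value (say
  `NCBItaxon:9606`) additionally types the bearer as `NCBITaxon_9606`.
  User files can augment or override any row, such as asserting that a
  tissue characteristic *is part of* the organism characteristic.
- **IRI minting.** Individuals get IRIs of the form
  `<base IRI>/<type>/<counter>`, counters starting at 1 per type in order
  of creation, each element minted exactly once.
- **Design enrichment.** Study groups — one per distinct combination of
  factor levels, with their sizes — are not expressible in ISA-Tab at all;
  `isardf` infers them from the factor-value columns (which may live in
  study or assay files) and adds them to the output. Factor levels are
  linked to their factors, never to individual samples.
- **Design queries.** Six shipped SPARQL queries report factors and
  levels, level counts, group combinations and sizes, min/max group size,
  and whether the design is balanced (min = max); a CONSTRUCT query
  materialises the balanced-design annotation (STATO's *balanced design*
  class by default) idempotently, and flags designs whose prior annotation
  disagrees with the recomputed sizes.

A seeded fixture generator (`isardf.fixtures`) produces realistic
multi-assay archives with known ground truth, and a cell-level brute-force
oracle recomputes every design fact without the graph or RDF machinery, so
the whole pipeline is testable offline.

## Worked example

Generate a two-group archive (factor `dose` ∈ {low, high}, three samples
per level), convert it under the OBI mapping, and interrogate the design:

```sh
$ isardf fixture --seed 7 --out demo/archive
wrote archive with 1 study(ies), 6 samples to demo/archive

$ isardf convert --input demo/archive --base-iri http://example.org/demo/ \
    --framework obi --out demo/archive.ttl

$ isardf query --in demo/archive.ttl groups
study   combination     size
study01 dose=high       3
study01 dose=low        3

$ isardf query --in demo/archive.ttl minmax
study   min_size        max_size
study01 3       3

$ isardf query --in demo/archive.ttl balanced
study   balanced
study01 True

$ isardf annotate-design --in demo/archive.ttl --out demo/annotated.ttl \
    --report demo/report.txt
$ cat demo/report.txt
study01 balanced=True   min=3   max=3
```

The two rows under `groups` are the inferred study groups: every distinct
factor-level combination with the count of member samples. Because the
minimum and maximum group sizes coincide the design is balanced, and the
annotation step adds exactly one triple typing the study-design individual
with the balanced-design class; re-running it adds nothing. The same
library calls are available in Python (`isardf.convert_archive`,
`isardf.q_group_sizes`, `isardf.annotate_balanced`, …).

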