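# Methods

## The model: ISA-Tab tables as a typed experiment DAG

An ISA-Tab archive is one investigation file plus one table file per
study and per assay. The underlying model is a directed acyclic graph
whose nodes are material entities (source, sample, extract, labeled
extract) or data files, connected through processes (applications of
declared protocols). Each table row is a walk through that graph, left to
right; column kinds come from a small fixed vocabulary recognised
case-insensitively, with bracket qualifiers (`Characteristics[x]`,
`Factor Value[x]`, `Parameter Value[x]`, `Comment[x]`) kept verbatim
because their text (e.g. `OBI:organism`) matters downstream.

**Identity rules.** Materials and data files are identified by
*(kind, name)*, scoped to the whole investigation: this is what joins a
study table and its assay tables on shared sample names. A process is
identified by *(protocol name, canonicalised parameter values, input
keys, output keys)* computed after row assembly, so identical rows merge
into one application while rows differing in any component stay separate
(two sources feeding one sample through the same protocol are two
applications). Acyclicity is enforced with a cycle check (networkx) after
every build and merge; a cyclic table is a hard structural error.

**Row segmentation.** Within a row, each maximal run of non-empty
`Protocol REF` cells between two non-empty node cells yields one process
per protocol; runs longer than one are chained through anonymous per-row
intermediate materials (named from row and column indices), because every
process must have explicit inputs and outputs. Empty node cells are
skipped for that row, so a process whose nominal output cell is blank
attaches to the next non-empty node on the right. A protocol run with no
node on one side is dropped with a warning. Qualifier columns attach
leftward: characteristics to the nearest node column, parameter values to
the nearest `Protocol REF`, `Unit` and `Term Source REF`/`Term Accession
Number` to the nearest annotatable cell (a unit may carry its own
term-source pair). A characteristic repeated with a different value for
the same material is kept as a multi-valued attribute with a warning —
the format does not say whether it is an error, and dropping data
silently would be worse.

**Process classification.** All-material inputs and outputs →
material-to-material; material in with any data out → material-to-data;
all-data → data-to-data. A mixed case that fits none of the three is
bucketed `MIXED` and flagged in the validation messages rather than
silently forced into a category.

## Mapping files and type resolution

The conversion engine is deliberately ignorant of any ontology. All
classes and properties are resolved through an ordered list of delimited
mapping files (tab or comma, sniffed per file): 3-field rows type ISA
elements (and double as the property vocabulary), 7-field rows add
specific property edges whose object is either a class IRI or a reference
to another ISA element. Context-dependent typing is encoded as a
parenthesised suffix on the element (`Protocol REF (study)`), keeping the
3-field arity. Precedence is: later file wins; within one file a
context-specific row beats a context-free one; an exact bracket-qualified
element beats its bare form. Resolution is total — an unmapped element
falls back to a deterministic IRI in a configurable ISA vocabulary
namespace (default `http://purl.org/isaterms/`), so conversion never
fails for lack of a mapping.

Packaged defaults: `isa` (a one-to-one rendering of the ISA-Tab 1.0
vocabulary into the ISA namespace — our own enumeration, flagged as such
in the file), `obi` (the OBI classes with established correspondences:
assay, material processing vs planned process for study/assay protocol
references, the organism category, specimen; plus STATO's balanced-design
class under the entry `balanced design`), `sio` and `provo` (generic
attribute/provenance properties). Structural properties (has factor/
level/group/member/size, has input/output, …) default to the ISA
namespace and may be overridden like any row; the shipped SPARQL queries
address the default namespace.

## Conversion and IRI policy

IRIs follow `<base>/<type>/<counter>`; counters start at 1 per type and
increase by one per newly minted element, an element key being minted at
most once per run. Traversal order is deterministic — investigation,
then studies in declared order, then materials/data/processes in
first-appearance (row-major) order, then factor levels in declaration ×
lexicographic order, then groups in canonical combination order — so
converting the same archive twice yields byte-identical canonical
N-Triples (sorted N-Triples; no blank nodes are ever emitted). Row
permutations that preserve element identity change counter assignment but
not the statement count or the identity-level structure.

Attribute emission: a characteristic or parameter value whose term
resolves, whose category resolves through the mapping set, or which
participates in a property mapping becomes a typed value individual
(category class, plus the value's own term IRI when annotated, plus
units); otherwise the bearer gets a plain literal object. This keeps
hand-entered free-text attributes lightweight while giving annotated ones
first-class individuals that specific property edges (e.g. tissue
part-of organism) can connect. An organism characteristic with a resolved
term additionally types the bearer itself (a source annotated
`NCBItaxon:9606` *is a* `NCBITaxon_9606`).

**Study groups.** Each sample's factor vector is the union of its
factor-value assignments across study and assay origins (anchored to the
row's leftmost sample node, else leftmost material — a deterministic
choice the format itself does not fix). Conflicting levels for one
(sample, factor) are a hard validation error, because group membership
would be ambiguous. Samples covering *all* declared factors are grouped
by canonical vector; partially assigned samples are excluded and listed
in the conversion messages, which keeps the groups a true partition of
the fully assigned samples. Groups link to their factor-level
individuals and carry an integer size literal; no sample→factor-value
triple is ever emitted, since factor values may legitimately live at
study or assay level depending on the design.

**Balanced-design annotation.** Balance is min group size = max group
size per study. The CONSTRUCT query types the *study-design individual*
(one is minted per study; declared design descriptors annotate it) with
the balanced-design class from the mapping entry or `--balanced-class`
flag — no class IRI is hardcoded. The operation is idempotent, and a
design previously annotated balanced whose recomputed sizes disagree is
reported as a discrepancy, never retracted.

## Synthetic archives and the oracle

The generator emulates the classic transcription-profiling layout:
sources collected into samples in the study table, a per-sample assay
chain (extraction → labeling → hybridization by default, 1–3 steps)
ending in a raw data file, organism characteristics with NCBI taxonomy
annotations, and factor-value columns realising a configurable full
factorial design (default one 2-level factor, three samples per group —
small but structurally complete). Row order is shuffled by the seed to
exercise order independence; names are zero-padded so creation and
lexicographic order coincide. The random-design sampler draws 1–3
factors with 2–4 levels and per-group sizes 1–6, balanced or imbalanced,
with factor values placed in the study table, the assay table, or both.

What the fixtures do **not** emulate: measurement file contents (data
files are names only), pooling/splitting topologies beyond name reuse,
multi-valued characteristics, missing factor assignments, and the messier
quoting/encoding found in hand-edited archives. Passing tests therefore
demonstrate correctness of the recovery/conversion/query logic under
clean structure, not robustness to arbitrary real-world files (the parser
does handle CRLF, quoted cells, short rows and unknown sections).

The oracle, `brute_force_design`, recomputes factors, levels, groups,
sizes and balance directly from table cells — distinct factor-value
tuples per sample — sharing nothing with the graph, mapping or RDF code
beyond the cell parser. The test suite requires exact agreement between
the SPARQL suite over converted RDF and this oracle on 50 random designs;
the acceptance script repeats that measurement from a user-supplied seed.

## Numerical and degenerate-input choices

- Header matching is case-insensitive; unknown headers become `OTHER`
  and are preserved, as are unknown investigation sections.
- Short rows are padded with empty strings; trailing blank rows dropped;
  cells trimmed. Encoding is UTF-8 with LF or CRLF.
- Duplicate ontology-source prefixes: last declaration wins, with a
  logged warning.
- Group sizes are typed integer literals; labels plain strings; no
  language tags.
- Studies with no groups produce no min/max/balanced rows (rather than
  zeros); factors with no assigned level are omitted from level counts.
- Problem sizes in the shipped tests (group sizes ≤ 6, ≤ 3 factors,
  ≤ 4 levels) were chosen as the smallest designs that exercise every
  code path — grouping, imbalance, multi-factor crossing — while keeping
  the default suite fast.

## Known limitations

- No validation against ISA configurations/templates, and no writing of
  curated archives (the writer exists for round-trip testing of the
  generator's output).
- Legacy process-naming columns (`Assay Name`, `Data Transformation
  Name`, `Normalization Name`) map to `OTHER` and do not split process
  identity.
- No OWL reasoning, no triple-store loading, no remote SPARQL execution;
  ontology "lookup" is purely the declared source-reference bases.
- The ISA vocabulary IRIs are project-namespace stand-ins, configurable
  and documented in the mapping files so downstream users can substitute
  canonical ones.
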