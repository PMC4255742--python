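"""Seeded synthetic ISA-Tab archives with machine-readable ground truth.

The generator emulates the canonical transcription-profiling pattern:
sources collected into samples in the study table (with factor-value
columns realising a configurable balanced or imbalanced group design),
and an assay chain per sample — sample, extract, labeled extract, raw
data file — each step an application of a declared protocol.  The same
archive structure, written with a fixed seed, is byte-identical across
runs, and a JSON ground-truth file derived from the fixture spec alone
is written beside it.

:func:`brute_force_design` recomputes the design facts (factors, levels,
groups, sizes, balance) straight from the table cells, with no graph or
RDF machinery — it is the independent oracle the pipeline is tested
against.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import asdict, dataclass, field
from itertools import product
from pathlib import Path

from .errors import FixtureSpecError
from .isatab_io import (
    DATA_KINDS,
    MATERIAL_KINDS,
    AssayDeclaration,
    FactorDefinition,
    HeaderKind,
    Investigation,
    OntologyAnnotation,
    OntologySourceRef,
    ProtocolDefinition,
    Study,
    TableFile,
    parse_archive,
    recognize_header,
)

_CHAIN_OUTPUTS = {
    1: ["Raw Data File"],
    2: ["Extract Name", "Raw Data File"],
    3: ["Extract Name", "Labeled Extract Name", "Raw Data File"],
}

DEFAULT_ASSAY_CHAIN = ("nucleic acid extraction", "labeling", "hybridization")


@dataclass
class FixtureSpec:
    """Specification of one synthetic archive; the seed fully determines
    the output bytes."""

    n_studies: int = 1
    factors: list = field(default_factory=lambda: [("dose", ["low", "high"])])
    group_size: int | list[int] = 3
    assay_chain: tuple = DEFAULT_ASSAY_CHAIN
    annotate_organism: bool = True
    factor_values_in: str = "study"  # study | assay | both
    ontology_sources: list = field(
        default_factory=lambda: [
            ("NCBItaxon", "http://purl.obolibrary.org/obo/NCBITaxon_"),
            ("OBI", "http://purl.obolibrary.org/obo/OBI_"),
        ]
    )
    seed: int = 0

    def study_factors(self, i: int) -> list[tuple[str, list[str]]]:
        """Factors of study ``i``: either shared or a per-study list."""
        if self.factors and isinstance(self.factors[0], list):
            return self.factors[i % len(self.factors)]
        return list(self.factors)

    def sizes(self, factors) -> list[int]:
        n_combos = 1
        for _, levels in factors:
            n_combos *= len(levels)
        if isinstance(self.group_size, int):
            sizes = [self.group_size] * n_combos
        else:
            sizes = list(self.group_size)
            if len(sizes) != n_combos:
                raise FixtureSpecError(
                    f"size list has {len(sizes)} entries for {n_combos} "
                    "factor-level combinations"
                )
        if any(s < 1 for s in sizes):
            raise FixtureSpecError("group sizes must be positive")
        return sizes


@dataclass
class StudyGroundTruth:
    factors: dict[str, list[str]] = field(default_factory=dict)
    groups: list[dict] = field(default_factory=list)
    balanced: bool | None = None
    min_size: int | None = None
    max_size: int | None = None
    n_samples: int = 0
    node_counts: dict[str, int] = field(default_factory=dict)
    process_counts: dict[str, int] | None = None

    def design_facts(self) -> dict:
        """The design-only view compared against the oracle."""
        return {
            "factors": self.factors,
            "groups": self.groups,
            "balanced": self.balanced,
            "min_size": self.min_size,
            "max_size": self.max_size,
            "n_samples": self.n_samples,
        }


@dataclass
class GroundTruth:
    studies: dict[str, StudyGroundTruth] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            studies={k: StudyGroundTruth(**v) for k, v in raw["studies"].items()}
        )


def _expected_study_truth(spec: FixtureSpec, factors, sizes) -> StudyGroundTruth:
    combos = list(product(*[levels for _, levels in factors]))
    names = [name for name, _ in factors]
    groups = [
        {"combination": dict(sorted(zip(names, combo))), "size": size}
        for combo, size in zip(combos, sizes)
    ]
    groups.sort(key=lambda g: sorted(g["combination"].items()))
    n = sum(sizes)
    chain = len(spec.assay_chain)
    truth = StudyGroundTruth(
        factors={name: sorted(levels) for name, levels in factors},
        groups=groups,
        balanced=len(set(sizes)) == 1,
        min_size=min(sizes),
        max_size=max(sizes),
        n_samples=n,
        node_counts={
            "source": n,
            "sample": n,
            **({"extract": n} if chain >= 2 else {}),
            **({"labeled_extract": n} if chain >= 3 else {}),
            "raw": n,
        },
        # per sample: 1 collection + (chain-1) material steps, then 1 data step
        process_counts={
            "material_to_material": n * chain,
            "material_to_data": n,
        },
    )
    return truth


def generate_fixture(spec: FixtureSpec, out_dir: Path | str) -> GroundTruth:
    """Write a complete archive under ``out_dir`` and return (and write,
    as ``ground_truth.json``) its expected design facts."""
    if len(spec.assay_chain) not in _CHAIN_OUTPUTS:
        raise FixtureSpecError("assay_chain must have 1 to 3 steps")
    if spec.factor_values_in not in ("study", "assay", "both"):
        raise FixtureSpecError(f"bad factor_values_in: {spec.factor_values_in!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    inv = Investigation(
        identifier=f"inv{spec.seed}",
        title="synthetic multi-assay archive",
        ontology_sources=[
            OntologySourceRef(name, base, "1.0", f"{name} terms")
            for name, base in spec.ontology_sources
        ],
    )
    truth = GroundTruth()
    for si in range(spec.n_studies):
        sid = f"study{si + 1:02d}"
        factors = spec.study_factors(si)
        sizes = spec.sizes(factors)
        study = _build_study(spec, sid, factors, sizes, inv, rng)
        inv.studies.append(study)
        truth.studies[sid] = _expected_study_truth(spec, factors, sizes)
    write_isatab(inv, out_dir)
    (out_dir / "ground_truth.json").write_text(truth.to_json(), encoding="utf-8")
    return truth


def _build_study(spec, sid, factors, sizes, inv, rng) -> Study:
    combos = list(product(*[levels for _, levels in factors]))
    names = [name for name, _ in factors]
    study = Study(
        identifier=sid,
        title=f"synthetic study {sid}",
        file_name=f"s_{sid}.txt",
        design_descriptors=[
            OntologyAnnotation(text="parallel group design")
        ],
        factors=[
            FactorDefinition(name, OntologyAnnotation(text=name))
            for name in names
        ],
        protocols=[ProtocolDefinition("sample collection", OntologyAnnotation(text="sample collection"))]
        + [
            ProtocolDefinition(step, OntologyAnnotation(text=step))
            for step in spec.assay_chain
        ],
    )

    samples = []
    i = 0
    for combo, size in zip(combos, sizes):
        for _ in range(size):
            i += 1
            samples.append((f"{sid}.sam{i:03d}", dict(zip(names, combo))))

    # study table
    headers = ["Source Name"]
    if spec.annotate_organism:
        headers += ["Characteristics[OBI:organism]", "Term Source REF", "Term Accession Number"]
    headers += ["Protocol REF", "Sample Name"]
    fv_in_study = spec.factor_values_in in ("study", "both")
    if fv_in_study:
        headers += [f"Factor Value[{name}]" for name in names]
    study_rows = []
    for j, (sample, vector) in enumerate(samples, 1):
        row = [f"{sid}.src{j:03d}"]
        if spec.annotate_organism:
            row += ["Homo sapiens", "NCBItaxon", "9606"]
        row += ["sample collection", sample]
        if fv_in_study:
            row += [vector[name] for name in names]
        study_rows.append(row)
    rng.shuffle(study_rows)
    study.study_table = TableFile(
        study.file_name,
        [recognize_header(h, k) for k, h in enumerate(headers)],
        study_rows,
    )

    # assay table
    outputs = _CHAIN_OUTPUTS[len(spec.assay_chain)]
    aheaders = ["Sample Name"]
    for step, out in zip(spec.assay_chain, outputs):
        aheaders += ["Protocol REF", out]
    fv_in_assay = spec.factor_values_in in ("assay", "both")
    if fv_in_assay:
        aheaders += [f"Factor Value[{name}]" for name in names]
    suffixes = {"Extract Name": ".ext", "Labeled Extract Name": ".lex", "Raw Data File": ".raw.txt"}
    assay_rows = []
    for sample, vector in samples:
        row = [sample]
        for step, out in zip(spec.assay_chain, outputs):
            row += [step, sample + suffixes[out]]
        if fv_in_assay:
            row += [vector[name] for name in names]
        assay_rows.append(row)
    rng.shuffle(assay_rows)
    afile = f"a_{sid}_assay.txt"
    study.assays.append(
        AssayDeclaration(
            measurement=OntologyAnnotation(text="transcription profiling"),
            technology=OntologyAnnotation(text="DNA microarray"),
            file_name=afile,
            assay_table=TableFile(
                afile,
                [recognize_header(h, k) for k, h in enumerate(aheaders)],
                assay_rows,
            ),
        )
    )
    return study


_FACTOR_NAMES = ("dose", "agent", "diet", "timepoint", "strain")


def random_spec(rng: random.Random) -> FixtureSpec:
    """Draw a design from the tested envelope: 1-3 factors with 2-4
    levels each, per-group sizes 1-6, balanced or imbalanced, factor
    values placed in the study table, the assay table, or both."""
    n_factors = rng.randint(1, 3)
    factors = []
    for name in rng.sample(_FACTOR_NAMES, n_factors):
        n_levels = rng.randint(2, 4)
        factors.append((name, [f"{name}.l{j + 1}" for j in range(n_levels)]))
    n_combos = 1
    for _, levels in factors:
        n_combos *= len(levels)
    if rng.random() < 0.5:
        group_size: int | list[int] = rng.randint(1, 6)
    else:
        sizes = [rng.randint(1, 6) for _ in range(n_combos)]
        if len(set(sizes)) == 1:
            sizes[0] = sizes[0] % 6 + 1
        group_size = sizes
    return FixtureSpec(
        factors=factors,
        group_size=group_size,
        assay_chain=DEFAULT_ASSAY_CHAIN[: rng.randint(1, 3)],
        annotate_organism=rng.random() < 0.7,
        factor_values_in=rng.choice(["study", "assay", "both"]),
        seed=rng.randrange(2**31),
    )


# --- writer ---------------------------------------------------------------

def _annotation_columns(values: list[OntologyAnnotation]):
    return (
        [a.text for a in values],
        [a.accession for a in values],
        [a.source_ref for a in values],
    )


def write_isatab(investigation: Investigation, out_dir: Path | str) -> None:
    """Serialise the in-memory model back to an ISA-Tab archive such
    that re-parsing yields an equal model."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[list[str]] = []

    def section(label, *field_rows):
        rows.append([label])
        rows.extend(field_rows)

    srcs = investigation.ontology_sources
    section(
        "ONTOLOGY SOURCE REFERENCE",
        ["Term Source Name"] + [s.name for s in srcs],
        ["Term Source File"] + [s.file_or_base for s in srcs],
        ["Term Source Version"] + [s.version for s in srcs],
        ["Term Source Description"] + [s.description for s in srcs],
    )
    section(
        "INVESTIGATION",
        ["Investigation Identifier", investigation.identifier],
        ["Investigation Title", investigation.title],
    )
    for block in investigation.extra_sections:
        rows.extend([cell for cell in line.split("\t")] for line in block)
    for study in investigation.studies:
        section(
            "STUDY",
            ["Study Identifier", study.identifier],
            ["Study Title", study.title],
            ["Study File Name", study.file_name],
        )
        texts, accs, refs = _annotation_columns(study.design_descriptors)
        section(
            "STUDY DESIGN DESCRIPTORS",
            ["Study Design Type"] + texts,
            ["Study Design Type Term Accession Number"] + accs,
            ["Study Design Type Term Source REF"] + refs,
        )
        texts, accs, refs = _annotation_columns([f.type for f in study.factors])
        section(
            "STUDY FACTORS",
            ["Study Factor Name"] + [f.name for f in study.factors],
            ["Study Factor Type"] + texts,
            ["Study Factor Type Term Accession Number"] + accs,
            ["Study Factor Type Term Source REF"] + refs,
        )
        m_texts, m_accs, m_refs = _annotation_columns([a.measurement for a in study.assays])
        t_texts, t_accs, t_refs = _annotation_columns([a.technology for a in study.assays])
        section(
            "STUDY ASSAYS",
            ["Study Assay File Name"] + [a.file_name for a in study.assays],
            ["Study Assay Measurement Type"] + m_texts,
            ["Study Assay Measurement Type Term Accession Number"] + m_accs,
            ["Study Assay Measurement Type Term Source REF"] + m_refs,
            ["Study Assay Technology Type"] + t_texts,
            ["Study Assay Technology Type Term Accession Number"] + t_accs,
            ["Study Assay Technology Type Term Source REF"] + t_refs,
        )
        texts, accs, refs = _annotation_columns([p.type for p in study.protocols])
        section(
            "STUDY PROTOCOLS",
            ["Study Protocol Name"] + [p.name for p in study.protocols],
            ["Study Protocol Type"] + texts,
            ["Study Protocol Type Term Accession Number"] + accs,
            ["Study Protocol Type Term Source REF"] + refs,
            ["Study Protocol Parameters Name"]
            + [";".join(n.text for n in p.parameter_names) for p in study.protocols],
        )
        for block in study.extra_sections:
            rows.extend([cell for cell in line.split("\t")] for line in block)
    _write_rows(out_dir / "i_investigation.txt", rows)

    for study in investigation.studies:
        if study.study_table is not None and study.file_name:
            _write_table(out_dir / study.file_name, study.study_table)
        for assay in study.assays:
            if assay.assay_table is not None:
                _write_table(out_dir / assay.file_name, assay.assay_table)


def _write_rows(path: Path, rows: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerows(rows)


def _write_table(path: Path, table: TableFile) -> None:
    _write_rows(path, [[h.render() for h in table.headers]] + table.rows)


# --- brute-force oracle ---------------------------------------------------

def brute_force_design(archive: Path | str) -> GroundTruth:
    """Recompute the design facts of an archive straight from its table
    cells: no experiment graph, no RDF.  Factor vectors are read off the
    Factor Value columns anchored to each row's sample; groups are the
    distinct complete vectors over the declared factors."""
    inv = parse_archive(archive)
    truth = GroundTruth()
    for study in inv.studies:
        declared = study.factor_names()
        vectors: dict[str, dict[str, str]] = {}
        counts: dict[tuple, set] = {}
        tables = [t for t in [study.study_table] if t is not None]
        tables += [a.assay_table for a in study.assays if a.assay_table is not None]
        for table in tables:
            sample_cols = [h.position for h in table.headers if h.kind is HeaderKind.SAMPLE_NAME]
            fv_cols = [
                (h.position, h.qualifier)
                for h in table.headers
                if h.kind is HeaderKind.FACTOR_VALUE and h.qualifier in declared
            ]
            for row in table.rows:
                sample = next((row[c] for c in sample_cols if row[c]), "")
                if not sample:
                    continue
                vec = vectors.setdefault(sample, {})
                for col, factor in fv_cols:
                    if row[col]:
                        vec[factor] = row[col]
            for h in table.headers:
                name_cell = None
                if h.kind in MATERIAL_KINDS:
                    name_cell = ("material", h.kind)
                elif h.kind in DATA_KINDS:
                    name_cell = ("data", h.kind)
                if name_cell is None:
                    continue
                for row in table.rows:
                    if row[h.position]:
                        counts.setdefault(name_cell, set()).add(row[h.position])
        st = StudyGroundTruth(n_samples=len(vectors))
        for factor in declared:
            levels = sorted({v[factor] for v in vectors.values() if factor in v})
            if levels:
                st.factors[factor] = levels
        groups: dict[tuple, int] = {}
        for vec in vectors.values():
            if declared and set(vec) == set(declared):
                combo = tuple(sorted(vec.items()))
                groups[combo] = groups.get(combo, 0) + 1
        st.groups = [
            {"combination": dict(combo), "size": size}
            for combo, size in sorted(groups.items())
        ]
        if groups:
            sizes = list(groups.values())
            st.min_size, st.max_size = min(sizes), max(sizes)
            st.balanced = st.min_size == st.max_size
        kind_names = {
            HeaderKind.SOURCE_NAME: "source",
            HeaderKind.SAMPLE_NAME: "sample",
            HeaderKind.EXTRACT_NAME: "extract",
            HeaderKind.LABELED_EXTRACT_NAME: "labeled_extract",
            HeaderKind.RAW_DATA_FILE: "raw",
            HeaderKind.DERIVED_DATA_FILE: "derived",
            HeaderKind.OTHER_DATA_FILE: "other",
        }
        for (_, kind), names in counts.items():
            st.node_counts[kind_names[kind]] = len(names)
        truth.studies[study.identifier] = st
    return truth
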