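"""Reading ISA-Tab archives into a faithful in-memory model.

An ISA-Tab archive is one *investigation* file (``i_*.txt``) holding
project context plus declarations (ontology sources, studies, factors,
protocols, assays), and one tab-delimited table file per study
(``s_*.txt``) and per assay (``a_*.txt``).  Table columns fall into a
small fixed vocabulary: material/data node names, ``Protocol REF``
process references, and qualifier columns (``Characteristics[...]``,
``Factor Value[...]``, ``Parameter Value[...]``, ``Unit``, ``Term Source
REF`` / ``Term Accession Number`` ontology-annotation pairs).

This module is purely syntactic: it recognises column kinds, resolves
ontology annotations against the declared source references, and keeps
every cell.  Graph recovery lives in :mod:`isardf.graph_analyser`.
"""

from __future__ import annotations

import csv
import io
import logging
import tempfile
import zipfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .errors import IsaTabFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "HeaderKind",
    "ColumnHeader",
    "OntologySourceRef",
    "OntologyAnnotation",
    "FactorDefinition",
    "ProtocolDefinition",
    "AssayDeclaration",
    "Study",
    "Investigation",
    "TableFile",
    "TableContext",
    "recognize_header",
    "parse_table_file",
    "parse_investigation",
    "parse_archive",
    "resolve_annotation",
]


class HeaderKind(Enum):
    SOURCE_NAME = "Source Name"
    SAMPLE_NAME = "Sample Name"
    EXTRACT_NAME = "Extract Name"
    LABELED_EXTRACT_NAME = "Labeled Extract Name"
    RAW_DATA_FILE = "Raw Data File"
    DERIVED_DATA_FILE = "Derived Data File"
    OTHER_DATA_FILE = "Data File"
    PROTOCOL_REF = "Protocol REF"
    CHARACTERISTICS = "Characteristics"
    FACTOR_VALUE = "Factor Value"
    PARAMETER_VALUE = "Parameter Value"
    TERM_SOURCE_REF = "Term Source REF"
    TERM_ACCESSION_NUMBER = "Term Accession Number"
    UNIT = "Unit"
    COMMENT = "Comment"
    LABEL = "Label"
    OTHER = "Other"


#: Column kinds that name a material node.
MATERIAL_KINDS = frozenset(
    {
        HeaderKind.SOURCE_NAME,
        HeaderKind.SAMPLE_NAME,
        HeaderKind.EXTRACT_NAME,
        HeaderKind.LABELED_EXTRACT_NAME,
    }
)

#: Column kinds that name a data node.
DATA_KINDS = frozenset(
    {
        HeaderKind.RAW_DATA_FILE,
        HeaderKind.DERIVED_DATA_FILE,
        HeaderKind.OTHER_DATA_FILE,
    }
)

#: Column kinds that name a graph node of either sort.
NODE_KINDS = MATERIAL_KINDS | DATA_KINDS

_EXACT_HEADERS = {
    "source name": HeaderKind.SOURCE_NAME,
    "sample name": HeaderKind.SAMPLE_NAME,
    "extract name": HeaderKind.EXTRACT_NAME,
    "labeled extract name": HeaderKind.LABELED_EXTRACT_NAME,
    "raw data file": HeaderKind.RAW_DATA_FILE,
    "raw spectral data file": HeaderKind.RAW_DATA_FILE,
    "array data file": HeaderKind.RAW_DATA_FILE,
    "derived data file": HeaderKind.DERIVED_DATA_FILE,
    "derived spectral data file": HeaderKind.DERIVED_DATA_FILE,
    "derived array data file": HeaderKind.DERIVED_DATA_FILE,
    "image file": HeaderKind.OTHER_DATA_FILE,
    "protocol ref": HeaderKind.PROTOCOL_REF,
    "term source ref": HeaderKind.TERM_SOURCE_REF,
    "term accession number": HeaderKind.TERM_ACCESSION_NUMBER,
    "unit": HeaderKind.UNIT,
    "label": HeaderKind.LABEL,
}

_BRACKET_HEADERS = {
    "characteristics": HeaderKind.CHARACTERISTICS,
    "factor value": HeaderKind.FACTOR_VALUE,
    "parameter value": HeaderKind.PARAMETER_VALUE,
    "comment": HeaderKind.COMMENT,
}


@dataclass(frozen=True)
class ColumnHeader:
    kind: HeaderKind
    qualifier: str = ""
    position: int = 0

    def render(self) -> str:
        """Canonical header text (inverse of :func:`recognize_header` on
        the fixed vocabulary)."""
        if self.kind in (
            HeaderKind.CHARACTERISTICS,
            HeaderKind.FACTOR_VALUE,
            HeaderKind.PARAMETER_VALUE,
            HeaderKind.COMMENT,
        ):
            return f"{self.kind.value}[{self.qualifier}]"
        if self.kind is HeaderKind.OTHER:
            return self.qualifier or "Other"
        return self.kind.value

    def element_form(self) -> str:
        """The ISA syntactic-element string used for mapping lookups,
        e.g. ``Characteristics[OBI:organism]``."""
        return self.render()


def recognize_header(text: str, position: int = 0) -> ColumnHeader:
    """Classify one table header cell.

    Matching is case-insensitive on the fixed vocabulary; the bracket
    qualifier (text between the first ``[`` and the last ``]``) is kept
    verbatim.  Unknown or malformed headers degrade to ``OTHER`` with the
    raw text preserved in ``qualifier`` — this function never fails.
    """
    raw = text.strip()
    low = raw.lower()
    if low in _EXACT_HEADERS:
        return ColumnHeader(_EXACT_HEADERS[low], "", position)
    if "[" in raw:
        prefix = raw[: raw.index("[")].strip().lower()
        kind = _BRACKET_HEADERS.get(prefix)
        if kind is not None:
            if raw.endswith("]"):
                qualifier = raw[raw.index("[") + 1 : raw.rindex("]")].strip()
                if qualifier:
                    return ColumnHeader(kind, qualifier, position)
            logger.warning("malformed bracket qualifier in header %r", raw)
    return ColumnHeader(HeaderKind.OTHER, raw, position)


@dataclass
class OntologySourceRef:
    name: str
    file_or_base: str = ""
    version: str = ""
    description: str = ""


@dataclass
class OntologyAnnotation:
    """A possibly ontology-backed value: free text plus an optional
    (source, accession) pair resolved to an absolute IRI when possible."""

    text: str = ""
    source_ref: str = ""
    accession: str = ""
    resolved_iri: str = ""

    def is_empty(self) -> bool:
        return not (self.text or self.source_ref or self.accession)


EMPTY_ANNOTATION = OntologyAnnotation()


def resolve_annotation(
    value: str,
    source: str,
    accession: str,
    sources: list[OntologySourceRef],
) -> OntologyAnnotation:
    """Build an :class:`OntologyAnnotation` from three table cells.

    An absolute accession (http/https/urn) is taken as the IRI directly;
    a local accession is absolutised against the matching declared
    source's base; with no match the annotation degrades to a literal.
    """
    value = value.strip()
    source = source.strip()
    accession = accession.strip()
    if not (value or source or accession):
        return OntologyAnnotation()
    resolved = ""
    if accession:
        if accession.startswith(("http://", "https://", "urn:")):
            resolved = accession
        else:
            for ref in sources:
                if ref.name == source and ref.file_or_base:
                    resolved = ref.file_or_base + accession
                    break
    return OntologyAnnotation(value, source, accession, resolved)


@dataclass
class FactorDefinition:
    name: str
    type: OntologyAnnotation = field(default_factory=OntologyAnnotation)


@dataclass
class ProtocolDefinition:
    name: str
    type: OntologyAnnotation = field(default_factory=OntologyAnnotation)
    parameter_names: list[OntologyAnnotation] = field(default_factory=list)


class TableContext(Enum):
    STUDY = "study"
    ASSAY = "assay"


@dataclass
class TableFile:
    path: str
    headers: list[ColumnHeader] = field(default_factory=list)
    rows: list[list[str]] = field(default_factory=list)


@dataclass
class AssayDeclaration:
    measurement: OntologyAnnotation
    technology: OntologyAnnotation
    file_name: str
    assay_table: TableFile | None = None


@dataclass
class Study:
    identifier: str
    title: str = ""
    file_name: str = ""
    design_descriptors: list[OntologyAnnotation] = field(default_factory=list)
    factors: list[FactorDefinition] = field(default_factory=list)
    protocols: list[ProtocolDefinition] = field(default_factory=list)
    study_table: TableFile | None = None
    assays: list[AssayDeclaration] = field(default_factory=list)
    extra_sections: list[list[str]] = field(default_factory=list)

    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def protocol_names(self) -> list[str]:
        return [p.name for p in self.protocols]


@dataclass
class Investigation:
    identifier: str = ""
    title: str = ""
    ontology_sources: list[OntologySourceRef] = field(default_factory=list)
    studies: list[Study] = field(default_factory=list)
    extra_sections: list[list[str]] = field(default_factory=list)


# --- low-level tab-delimited reading -------------------------------------

def _read_rows(path: Path) -> list[list[str]]:
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise IsaTabFormatError(f"cannot read {path}: {exc}") from exc
    reader = csv.reader(io.StringIO(text, newline=""), delimiter="\t")
    return [[cell.strip() for cell in row] for row in reader]


def parse_table_file(path: Path | str, context: TableContext) -> TableFile:
    """Parse one study or assay table: a header row plus data rows.

    Rows shorter than the header are padded with empty strings; trailing
    all-blank rows are dropped; cells are whitespace-trimmed.  An empty
    or header-only file yields zero rows.
    """
    path = Path(path)
    raw = _read_rows(path)
    while raw and not any(raw[-1]):
        raw.pop()
    if not raw:
        return TableFile(path.name)
    headers = [recognize_header(cell, i) for i, cell in enumerate(raw[0])]
    width = len(headers)
    rows = []
    for cells in raw[1:]:
        if not any(cells):
            continue
        cells = list(cells[:width]) + [""] * max(0, width - len(cells))
        rows.append(cells)
    return TableFile(path.name, headers, rows)


# --- investigation file ---------------------------------------------------

_SECTIONS = {
    "ONTOLOGY SOURCE REFERENCE",
    "INVESTIGATION",
    "STUDY",
    "STUDY DESIGN DESCRIPTORS",
    "STUDY FACTORS",
    "STUDY ASSAYS",
    "STUDY PROTOCOLS",
}


def _is_section_row(row: list[str]) -> bool:
    first = row[0].strip()
    return bool(first) and first == first.upper() and any(c.isalpha() for c in first) and not any(
        c.strip() for c in row[1:]
    )


def _section_blocks(rows: list[list[str]]):
    """Split investigation rows into ``(section-label, field-rows)``
    blocks.  Unknown sections are kept as opaque blocks with label
    ``None`` (their header row included verbatim), never an error."""
    blocks: list[tuple[str | None, list[list[str]]]] = []
    current: tuple[str | None, list[list[str]]] | None = None
    for row in rows:
        if not any(cell.strip() for cell in row):
            continue
        if _is_section_row(row):
            label = row[0].strip()
            if label in _SECTIONS:
                current = (label, [])
            else:
                logger.warning("unknown investigation section %r kept as comment", label)
                current = (None, [row])
            blocks.append(current)
            continue
        if current is None:
            current = (None, [row])
            blocks.append(current)
        else:
            current[1].append(row)
    return blocks


def _fields(block_rows: list[list[str]]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for row in block_rows:
        out[row[0]] = [c for c in row[1:]]
    return out


def _column(fields: dict[str, list[str]], label: str, i: int) -> str:
    vals = fields.get(label, [])
    return vals[i].strip() if i < len(vals) else ""


def _entity_count(fields: dict[str, list[str]], *labels: str) -> int:
    n = 0
    for label in labels:
        vals = fields.get(label, [])
        while vals and not vals[-1].strip():
            vals = vals[:-1]
        n = max(n, len(vals))
    return n


def parse_investigation(path: Path | str, load_tables: bool = True) -> Investigation:
    """Parse an investigation file and (by default) the study and assay
    tables it references.

    Raises :class:`IsaTabFormatError` if the file lacks a STUDY section
    or references a table file that does not exist next to it.
    """
    path = Path(path)
    if not path.exists():
        raise IsaTabFormatError(f"investigation file not found: {path}")
    rows = _read_rows(path)
    inv = Investigation()
    study: Study | None = None
    seen_study = False
    for label, block in _section_blocks(rows):
        fields = _fields(block)
        if label is None:
            (study.extra_sections if study else inv.extra_sections).append(
                ["\t".join(r) for r in block]
            )
        elif label == "ONTOLOGY SOURCE REFERENCE":
            n = _entity_count(fields, "Term Source Name")
            for i in range(n):
                ref = OntologySourceRef(
                    name=_column(fields, "Term Source Name", i),
                    file_or_base=_column(fields, "Term Source File", i),
                    version=_column(fields, "Term Source Version", i),
                    description=_column(fields, "Term Source Description", i),
                )
                if not ref.name:
                    continue
                if any(s.name == ref.name for s in inv.ontology_sources):
                    logger.warning(
                        "duplicate ontology source %r: last declaration wins", ref.name
                    )
                    inv.ontology_sources = [
                        s for s in inv.ontology_sources if s.name != ref.name
                    ]
                inv.ontology_sources.append(ref)
        elif label == "INVESTIGATION":
            inv.identifier = _column(fields, "Investigation Identifier", 0)
            inv.title = _column(fields, "Investigation Title", 0)
        elif label == "STUDY":
            seen_study = True
            study = Study(
                identifier=_column(fields, "Study Identifier", 0),
                title=_column(fields, "Study Title", 0),
                file_name=_column(fields, "Study File Name", 0),
            )
            inv.studies.append(study)
        elif study is None:
            raise IsaTabFormatError(f"section {label} before any STUDY section")
        elif label == "STUDY DESIGN DESCRIPTORS":
            n = _entity_count(fields, "Study Design Type")
            for i in range(n):
                study.design_descriptors.append(
                    resolve_annotation(
                        _column(fields, "Study Design Type", i),
                        _column(fields, "Study Design Type Term Source REF", i),
                        _column(fields, "Study Design Type Term Accession Number", i),
                        inv.ontology_sources,
                    )
                )
        elif label == "STUDY FACTORS":
            n = _entity_count(fields, "Study Factor Name")
            for i in range(n):
                name = _column(fields, "Study Factor Name", i)
                if not name:
                    continue
                study.factors.append(
                    FactorDefinition(
                        name,
                        resolve_annotation(
                            _column(fields, "Study Factor Type", i),
                            _column(fields, "Study Factor Type Term Source REF", i),
                            _column(fields, "Study Factor Type Term Accession Number", i),
                            inv.ontology_sources,
                        ),
                    )
                )
        elif label == "STUDY ASSAYS":
            n = _entity_count(fields, "Study Assay File Name")
            for i in range(n):
                fname = _column(fields, "Study Assay File Name", i)
                if not fname:
                    continue
                study.assays.append(
                    AssayDeclaration(
                        measurement=resolve_annotation(
                            _column(fields, "Study Assay Measurement Type", i),
                            _column(fields, "Study Assay Measurement Type Term Source REF", i),
                            _column(
                                fields,
                                "Study Assay Measurement Type Term Accession Number",
                                i,
                            ),
                            inv.ontology_sources,
                        ),
                        technology=resolve_annotation(
                            _column(fields, "Study Assay Technology Type", i),
                            _column(fields, "Study Assay Technology Type Term Source REF", i),
                            _column(
                                fields,
                                "Study Assay Technology Type Term Accession Number",
                                i,
                            ),
                            inv.ontology_sources,
                        ),
                        file_name=fname,
                    )
                )
        elif label == "STUDY PROTOCOLS":
            n = _entity_count(fields, "Study Protocol Name")
            for i in range(n):
                name = _column(fields, "Study Protocol Name", i)
                if not name:
                    continue
                params = [
                    p.strip()
                    for p in _column(fields, "Study Protocol Parameters Name", i).split(";")
                    if p.strip()
                ]
                study.protocols.append(
                    ProtocolDefinition(
                        name,
                        resolve_annotation(
                            _column(fields, "Study Protocol Type", i),
                            _column(fields, "Study Protocol Type Term Source REF", i),
                            _column(
                                fields, "Study Protocol Type Term Accession Number", i
                            ),
                            inv.ontology_sources,
                        ),
                        [OntologyAnnotation(text=p) for p in params],
                    )
                )
    if not seen_study:
        raise IsaTabFormatError(f"{path.name}: missing STUDY section")
    if load_tables:
        base = path.parent
        for study in inv.studies:
            if study.file_name:
                tpath = base / study.file_name
                if not tpath.exists():
                    raise IsaTabFormatError(
                        f"referenced study table not found: {study.file_name}"
                    )
                study.study_table = parse_table_file(tpath, TableContext.STUDY)
            for assay in study.assays:
                apath = base / assay.file_name
                if not apath.exists():
                    raise IsaTabFormatError(
                        f"referenced assay table not found: {assay.file_name}"
                    )
                assay.assay_table = parse_table_file(apath, TableContext.ASSAY)
    return inv


def parse_archive(path: Path | str) -> Investigation:
    """Parse an archive given as a directory, a zip file, or the
    investigation file itself."""
    path = Path(path)
    if path.is_file() and path.suffix == ".zip":
        with tempfile.TemporaryDirectory() as tmp:
            with zipfile.ZipFile(path) as zf:
                zf.extractall(tmp)
            return parse_archive(Path(tmp))
    if path.is_dir():
        candidates = sorted(path.glob("i_*.txt"))
        if not candidates:
            raise IsaTabFormatError(f"no investigation file (i_*.txt) in {path}")
        return parse_investigation(candidates[0])
    return parse_investigation(path)
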