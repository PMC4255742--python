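"""Mapping files: ISA syntactic elements to ontology classes and properties.

The conversion engine is decoupled from any particular semantic
framework.  Delimited mapping files (tab or comma, sniffed per file)
carry two row shapes:

* **type rows** — exactly three fields ``element, class label, class
  IRI``; they type the individuals produced for an ISA element (and
  double as the property vocabulary: a row whose element is a property
  name such as ``has input`` sets the property IRI the converter uses);
* **property rows** — seven fields ``subject element, subject label,
  subject IRI, property label, property IRI, object label, object``
  where the object is either a class IRI or a reference to another ISA
  element (resolved to that element's class at conversion time).

Context-dependent typing (the same element meaning different things in
study and assay tables) is written as a parenthesised suffix on the
element, e.g. ``Protocol REF (study)``.

Four default mapping sets ship with the package: ``isa`` (a one-to-one
rendering of the ISA vocabulary into a configurable namespace), ``obi``,
``sio`` and ``provo``.  Later files override earlier ones per (element,
context); a context-specific row beats a context-free one.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import MappingFormatError
from .isatab_io import TableContext
from .vocab import ISA_TERMS, fallback_iri

FRAMEWORKS = ("isa", "obi", "sio", "provo")

_CONTEXT_SUFFIX = re.compile(r"\((study|assay)\)\s*$", re.IGNORECASE)


def _is_absolute(iri: str) -> bool:
    return iri.startswith(("http://", "https://", "urn:"))


def _split_context(element: str):
    m = _CONTEXT_SUFFIX.search(element)
    if m:
        return element[: m.start()].strip(), TableContext(m.group(1).lower())
    return element.strip(), None


@dataclass(frozen=True)
class TypeMapping:
    isa_element: str
    class_label: str
    class_iri: str
    context: TableContext | None = None  # None means ANY


@dataclass(frozen=True)
class PropertyMapping:
    subject_element: str
    subject_label: str
    subject_class_iri: str
    property_label: str
    property_iri: str
    object_label: str
    object_iri: str = ""
    object_element: str = ""


def parse_mapping_file(path: Path | str) -> list[TypeMapping | PropertyMapping]:
    """Parse one mapping file.  Blank lines and ``#`` comments are
    skipped; a bad arity or a relative IRI in an IRI field raises
    :class:`MappingFormatError` with the line number."""
    path = Path(path)
    return parse_mapping_text(path.read_text(encoding="utf-8"), str(path))


def parse_mapping_text(text: str, origin: str = "<string>"):
    lines = [ln for ln in text.splitlines()]
    delimiter = None
    for ln in lines:
        if ln.strip() and not ln.lstrip().startswith("#"):
            delimiter = "\t" if ln.count("\t") >= ln.count(",") else ","
            break
    if delimiter is None:
        return []
    mappings: list[TypeMapping | PropertyMapping] = []
    for lineno, ln in enumerate(lines, 1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        fields = next(csv.reader(io.StringIO(ln), delimiter=delimiter))
        fields = [f.strip() for f in fields]
        while fields and not fields[-1]:
            fields.pop()
        if len(fields) == 3:
            element, label, iri = fields
            if not _is_absolute(iri):
                raise MappingFormatError(
                    f"{origin}:{lineno}: class IRI is not absolute: {iri!r}"
                )
            name, context = _split_context(element)
            mappings.append(TypeMapping(name, label, iri, context))
        elif len(fields) == 7:
            subj, subj_label, subj_iri, prop_label, prop_iri, obj_label, obj = fields
            if subj_iri and not _is_absolute(subj_iri):
                raise MappingFormatError(
                    f"{origin}:{lineno}: subject IRI is not absolute: {subj_iri!r}"
                )
            if not _is_absolute(prop_iri):
                raise MappingFormatError(
                    f"{origin}:{lineno}: property IRI is not absolute: {prop_iri!r}"
                )
            if _is_absolute(obj):
                mappings.append(
                    PropertyMapping(
                        subj, subj_label, subj_iri, prop_label, prop_iri,
                        obj_label, object_iri=obj,
                    )
                )
            else:
                mappings.append(
                    PropertyMapping(
                        subj, subj_label, subj_iri, prop_label, prop_iri,
                        obj_label, object_element=obj,
                    )
                )
        else:
            raise MappingFormatError(
                f"{origin}:{lineno}: expected 3 fields (type mapping) or 7 "
                f"(property mapping), got {len(fields)}"
            )
    return mappings


@dataclass
class MappingSet:
    """Ordered mapping files; lookup precedence is last-file-wins per
    (element, context), with context-specific rows beating ANY rows."""

    files: list[list[TypeMapping | PropertyMapping]] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    namespace: str = ISA_TERMS

    @classmethod
    def load(
        cls,
        framework: str | None = None,
        extra_files: list[Path | str] = (),
        namespace: str = ISA_TERMS,
    ) -> "MappingSet":
        """Load the packaged ``isa`` base vocabulary, then an optional
        framework default (obi/sio/provo), then user files, in order."""
        ms = cls(namespace=namespace)
        ms.add_packaged("isa")
        if framework and framework != "isa":
            if framework not in FRAMEWORKS:
                raise MappingFormatError(f"unknown framework {framework!r}")
            ms.add_packaged(framework)
        for f in extra_files:
            ms.add_file(f)
        return ms

    def add_packaged(self, name: str) -> None:
        ref = resources.files("isardf.mappings").joinpath(f"{name}.csv")
        self.files.append(parse_mapping_text(ref.read_text(encoding="utf-8"), f"{name}.csv"))
        self.provenance.append(f"packaged:{name}.csv")

    def add_file(self, path: Path | str) -> None:
        self.files.append(parse_mapping_file(path))
        self.provenance.append(str(path))

    def lookup_type(
        self, isa_element: str, context: TableContext | None = None
    ) -> TypeMapping | None:
        """Most specific, latest-file type row for an element, or None
        (no fallback minting)."""
        return _best_row(isa_element, context, self)


def resolve_type(
    isa_element: str,
    context: TableContext | None,
    mappings: MappingSet,
) -> str:
    """Resolve an ISA element to a class IRI.

    Precedence: exact element string (bracket qualifier included) before
    the bare element name; a context-specific row before a context-free
    one; later files before earlier ones.  With no match at all, a
    deterministic fallback IRI is minted in the configured ISA
    vocabulary namespace — this function is total.
    """
    candidates = [isa_element]
    if "[" in isa_element:
        candidates.append(isa_element[: isa_element.index("[")].strip())
    for cand in candidates:
        hit = _best_row(cand, context, mappings)
        if hit is not None:
            return hit.class_iri
    return fallback_iri(isa_element, mappings.namespace)


def _best_row(element: str, context, mappings: MappingSet) -> TypeMapping | None:
    # later file wins; within one file, a context-specific row beats ANY
    best = None
    best_key = (-1, -1)
    for rank, file in enumerate(mappings.files):
        for m in file:
            if not isinstance(m, TypeMapping) or m.isa_element != element:
                continue
            if m.context is not None and m.context != context:
                continue
            key = (rank, 1 if m.context is not None else 0)
            if key >= best_key:
                best, best_key = m, key
    return best


def resolve_property(name: str, mappings: MappingSet) -> str:
    """Property IRIs go through the same table as types (3-field rows
    whose element is the property name)."""
    return resolve_type(name, None, mappings)


def property_edges_for(
    subject_element: str, mappings: MappingSet
) -> list[PropertyMapping]:
    """All property rows for a subject element, in file order, with
    element-reference objects resolved to class IRIs (kept alongside the
    raw element reference).  Unresolvable references are skipped with no
    error (resolution is total, so this only guards empty objects)."""
    out = []
    for file in mappings.files:
        for m in file:
            if isinstance(m, PropertyMapping) and m.subject_element == subject_element:
                if m.object_iri:
                    out.append(m)
                elif m.object_element:
                    resolved = resolve_type(m.object_element, None, mappings)
                    out.append(
                        PropertyMapping(
                            m.subject_element, m.subject_label, m.subject_class_iri,
                            m.property_label, m.property_iri, m.object_label,
                            object_iri=resolved, object_element=m.object_element,
                        )
                    )
    return out
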