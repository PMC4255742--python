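"""Recovering the experiment graph from ISA-Tab tables.

Each table row is one path through the experiment's directed acyclic
graph: material and data node columns alternate with ``Protocol REF``
columns, and every row-level protocol application is a process with the
node to its left as input and the node to its right as output.  Element
identity follows the ISA conventions: materials and data files are
identified by their (kind, name) pair, so the same sample name in the
study and an assay table is one node; a process is identified by the
full tuple (protocol name, parameter values, inputs, outputs), so two
rows naming the same protocol may or may not be the same process
application.

Qualifier columns attach leftward: ``Characteristics[...]`` to the
nearest node column, ``Parameter Value[...]`` to the nearest ``Protocol
REF``, ``Unit`` and ``Term Source REF``/``Term Accession Number`` to the
nearest annotatable cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum

import networkx as nx

from .errors import GraphStructureError
from .isatab_io import (
    ColumnHeader,
    HeaderKind,
    OntologyAnnotation,
    Study,
    TableContext,
    TableFile,
    resolve_annotation,
)

logger = logging.getLogger(__name__)


class MaterialType(Enum):
    SOURCE = "source"
    SAMPLE = "sample"
    EXTRACT = "extract"
    LABELED_EXTRACT = "labeled_extract"
    OTHER_MATERIAL = "material"


class DataKind(Enum):
    RAW = "raw"
    DERIVED = "derived"
    OTHER = "other"


class ProcessCategory(Enum):
    MATERIAL_TO_MATERIAL = "material_to_material"
    MATERIAL_TO_DATA = "material_to_data"
    DATA_TO_DATA = "data_to_data"
    MIXED = "mixed"


_MATERIAL_BY_KIND = {
    HeaderKind.SOURCE_NAME: MaterialType.SOURCE,
    HeaderKind.SAMPLE_NAME: MaterialType.SAMPLE,
    HeaderKind.EXTRACT_NAME: MaterialType.EXTRACT,
    HeaderKind.LABELED_EXTRACT_NAME: MaterialType.LABELED_EXTRACT,
}

_DATA_BY_KIND = {
    HeaderKind.RAW_DATA_FILE: DataKind.RAW,
    HeaderKind.DERIVED_DATA_FILE: DataKind.DERIVED,
    HeaderKind.OTHER_DATA_FILE: DataKind.OTHER,
}


@dataclass
class AttributeValue:
    """A characteristic, factor value or parameter value with optional
    ontology annotations on both the value and its unit."""

    qualifier: str
    element_form: str
    value: OntologyAnnotation
    unit: OntologyAnnotation | None = None

    def key(self):
        unit = self.unit.text if self.unit else ""
        return (self.qualifier, self.value.text, self.value.resolved_iri, unit)

    def category_label(self) -> str:
        """Label part of a ``PREFIX:label`` qualifier (``organism`` from
        ``OBI:organism``)."""
        return self.qualifier.split(":", 1)[-1].strip()


@dataclass
class MaterialNode:
    name: str
    node_type: MaterialType
    characteristics: list[AttributeValue] = field(default_factory=list)
    declared_type_iri: str = ""

    def key(self):
        return ("material", self.node_type.value, self.name)


@dataclass
class DataNode:
    name: str
    data_kind: DataKind

    def key(self):
        return ("data", self.data_kind.value, self.name)


@dataclass
class ProcessNode:
    protocol_name: str
    parameter_values: list[AttributeValue] = field(default_factory=list)
    inputs: list[tuple] = field(default_factory=list)
    outputs: list[tuple] = field(default_factory=list)
    category: ProcessCategory | None = None
    context: TableContext = TableContext.STUDY

    def key(self):
        params = tuple(sorted(pv.key() for pv in self.parameter_values))
        return (
            "process",
            self.protocol_name,
            params,
            tuple(sorted(self.inputs)),
            tuple(sorted(self.outputs)),
        )


def element_key(element: MaterialNode | DataNode | ProcessNode) -> tuple:
    """Identity key of a graph element: (kind, name) for materials and
    data, the full application tuple for processes."""
    return element.key()


@dataclass
class FactorValueAssignment:
    sample_key: tuple
    factor_name: str
    level: OntologyAnnotation
    origin: TableContext

    def key(self):
        return (self.sample_key, self.factor_name, self.level.text, self.origin.value)


@dataclass
class ExperimentGraph:
    materials: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)
    processes: dict = field(default_factory=dict)
    edges: set = field(default_factory=set)
    factor_assignments: list[FactorValueAssignment] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def node(self, key: tuple):
        if key[0] == "material":
            return self.materials.get(key)
        if key[0] == "data":
            return self.data.get(key)
        return self.processes.get(key)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for key in list(self.materials) + list(self.data) + list(self.processes):
            g.add_node(key)
        g.add_edges_from(self.edges)
        return g

    def check_acyclic(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise GraphStructureError(f"experiment graph contains a cycle: {cycle}")

    def to_dot(self) -> str:
        """GraphViz DOT export for inspection (not a stable format)."""
        shapes = {"material": "ellipse", "data": "note", "process": "box"}
        lines = ["digraph experiment {"]
        ids: dict[tuple, str] = {}
        for key in list(self.materials) + list(self.data) + list(self.processes):
            ids[key] = f"n{len(ids)}"
            label = key[1] if key[0] == "process" else key[2]
            lines.append(f'  {ids[key]} [label="{label}" shape={shapes[key[0]]}];')
        for a, b in sorted(self.edges, key=repr):
            lines.append(f"  {ids[a]} -> {ids[b]};")
        lines.append("}")
        return "\n".join(lines)


# --- column wiring --------------------------------------------------------

_ANNOTATABLE = frozenset(
    {HeaderKind.CHARACTERISTICS, HeaderKind.FACTOR_VALUE, HeaderKind.PARAMETER_VALUE}
)


@dataclass
class _AttrCols:
    header: ColumnHeader
    source_col: int | None = None
    accession_col: int | None = None
    unit_col: int | None = None
    unit_source_col: int | None = None
    unit_accession_col: int | None = None
    anchor_col: int | None = None  # node or protocol column this qualifies


def _wire_columns(table: TableFile):
    """Statically associate qualifier columns with their anchors."""
    node_cols: list[ColumnHeader] = []
    proto_cols: list[ColumnHeader] = []
    attrs: dict[int, _AttrCols] = {}
    last_node: int | None = None
    last_proto: int | None = None
    last_attr: _AttrCols | None = None
    pending_unit_for: _AttrCols | None = None
    for h in table.headers:
        if h.kind in _MATERIAL_BY_KIND or h.kind in _DATA_BY_KIND:
            node_cols.append(h)
            last_node = h.position
            last_attr = None
        elif h.kind is HeaderKind.PROTOCOL_REF:
            proto_cols.append(h)
            last_proto = h.position
            last_attr = None
        elif h.kind in _ANNOTATABLE:
            ac = _AttrCols(h)
            if h.kind is HeaderKind.PARAMETER_VALUE:
                ac.anchor_col = last_proto
            else:
                ac.anchor_col = last_node
            attrs[h.position] = ac
            last_attr = ac
            pending_unit_for = None
        elif h.kind is HeaderKind.UNIT:
            if last_attr is not None:
                last_attr.unit_col = h.position
                pending_unit_for = last_attr
        elif h.kind is HeaderKind.TERM_SOURCE_REF:
            if pending_unit_for is not None:
                pending_unit_for.unit_source_col = h.position
            elif last_attr is not None:
                last_attr.source_col = h.position
        elif h.kind is HeaderKind.TERM_ACCESSION_NUMBER:
            if pending_unit_for is not None:
                pending_unit_for.unit_accession_col = h.position
            elif last_attr is not None:
                last_attr.accession_col = h.position
    return node_cols, proto_cols, attrs


def _cell(row: list[str], col: int | None) -> str:
    return row[col] if col is not None and col < len(row) else ""


def _attribute_from_row(row, ac: _AttrCols, sources) -> AttributeValue | None:
    text = _cell(row, ac.header.position)
    if not text:
        return None
    value = resolve_annotation(
        text, _cell(row, ac.source_col), _cell(row, ac.accession_col), sources
    )
    unit = None
    unit_text = _cell(row, ac.unit_col)
    if unit_text:
        unit = resolve_annotation(
            unit_text,
            _cell(row, ac.unit_source_col),
            _cell(row, ac.unit_accession_col),
            sources,
        )
    return AttributeValue(ac.header.qualifier, ac.header.element_form(), value, unit)


# --- graph construction ---------------------------------------------------

def build_graph(
    table: TableFile,
    study: Study,
    context: TableContext,
    ontology_sources=None,
) -> ExperimentGraph:
    """Build the experiment graph of one table file.

    Per row, node columns and ``Protocol REF`` columns are scanned left
    to right; each run of protocol references between two non-empty node
    cells yields one process application per protocol (runs longer than
    one are chained through anonymous intermediate materials).  Elements
    with equal identity keys across rows merge.
    """
    ontology_sources = ontology_sources if ontology_sources is not None else []
    graph = ExperimentGraph()
    node_cols, proto_cols, attrs = _wire_columns(table)
    declared_factors = set(study.factor_names())
    declared_protocols = set(study.protocol_names())
    seen_assignments = set()

    for row_idx, row in enumerate(table.rows):
        # ordered per-row events: (position, "node"/"proto", payload)
        events = []
        for h in node_cols:
            name = _cell(row, h.position)
            if not name:
                continue
            if h.kind in _MATERIAL_BY_KIND:
                node = MaterialNode(name, _MATERIAL_BY_KIND[h.kind])
            else:
                node = DataNode(name, _DATA_BY_KIND[h.kind])
            key = node.key()
            existing = graph.node(key)
            if existing is None:
                if key[0] == "material":
                    graph.materials[key] = node
                else:
                    graph.data[key] = node
                existing = node
            if isinstance(existing, MaterialNode):
                for ac in attrs.values():
                    if (
                        ac.header.kind is HeaderKind.CHARACTERISTICS
                        and ac.anchor_col == h.position
                    ):
                        attr = _attribute_from_row(row, ac, ontology_sources)
                        if attr is None:
                            continue
                        prior = [
                            c for c in existing.characteristics if c.qualifier == attr.qualifier
                        ]
                        if attr.key() not in {c.key() for c in existing.characteristics}:
                            if prior:
                                graph.warnings.append(
                                    f"material {name!r}: characteristic "
                                    f"{attr.qualifier!r} has multiple values "
                                    f"({prior[0].value.text!r}, {attr.value.text!r})"
                                )
                            existing.characteristics.append(attr)
                        if (
                            attr.category_label().lower() == "organism"
                            and attr.value.resolved_iri
                        ):
                            existing.declared_type_iri = attr.value.resolved_iri
            events.append((h.position, "node", key))
        for h in proto_cols:
            name = _cell(row, h.position)
            if not name:
                continue
            if name not in declared_protocols:
                graph.warnings.append(
                    f"row {row_idx}: Protocol REF {name!r} is not declared"
                )
            params = []
            for ac in attrs.values():
                if (
                    ac.header.kind is HeaderKind.PARAMETER_VALUE
                    and ac.anchor_col == h.position
                ):
                    attr = _attribute_from_row(row, ac, ontology_sources)
                    if attr is not None:
                        params.append(attr)
            events.append((h.position, "proto", (name, params)))
        events.sort(key=lambda e: e[0])

        # segment into processes
        pending: list[tuple[str, list]] = []
        last_node_key = None
        for pos, kind, payload in events:
            if kind == "node":
                if pending:
                    if last_node_key is None:
                        graph.warnings.append(
                            f"row {row_idx}: protocol(s) "
                            f"{[p[0] for p in pending]} have no input node; skipped"
                        )
                    else:
                        _chain(graph, pending, last_node_key, payload, context, row_idx, pos)
                    pending = []
                last_node_key = payload
            else:
                pending.append(payload)
        if pending:
            graph.warnings.append(
                f"row {row_idx}: protocol(s) {[p[0] for p in pending]} "
                "have no output node; skipped"
            )

        # factor values anchor to the row's sample (leftmost SAMPLE node,
        # else leftmost material node)
        anchor = None
        for pos, kind, payload in events:
            if kind == "node" and payload[0] == "material" and payload[1] == "sample":
                anchor = payload
                break
        if anchor is None:
            for pos, kind, payload in events:
                if kind == "node" and payload[0] == "material":
                    anchor = payload
                    break
        for ac in attrs.values():
            if ac.header.kind is not HeaderKind.FACTOR_VALUE:
                continue
            attr = _attribute_from_row(row, ac, ontology_sources)
            if attr is None:
                continue
            if anchor is None:
                graph.warnings.append(
                    f"row {row_idx}: factor value {attr.qualifier!r} has no "
                    "material node to bind to; dropped"
                )
                continue
            if attr.qualifier not in declared_factors:
                graph.warnings.append(
                    f"row {row_idx}: factor value {attr.qualifier!r} does not "
                    "match a declared factor"
                )
            fva = FactorValueAssignment(anchor, attr.qualifier, attr.value, context)
            if fva.key() not in seen_assignments:
                seen_assignments.add(fva.key())
                graph.factor_assignments.append(fva)

    for proc in graph.processes.values():
        proc.category = classify_process(proc, graph)
    graph.check_acyclic()
    return graph


def _chain(graph, protocols, input_key, output_key, context, row_idx, pos):
    """Emit one process per protocol in a run, chaining consecutive
    protocols through anonymous per-row intermediate materials."""
    keys = [input_key]
    for i in range(len(protocols) - 1):
        anon = MaterialNode(
            f"_intermediate_r{row_idx}_c{pos}_{i}", MaterialType.OTHER_MATERIAL
        )
        graph.materials.setdefault(anon.key(), anon)
        keys.append(anon.key())
    keys.append(output_key)
    for (name, params), inp, out in zip(protocols, keys[:-1], keys[1:]):
        proc = ProcessNode(name, params, [inp], [out], context=context)
        pkey = proc.key()
        graph.processes.setdefault(pkey, proc)
        graph.edges.add((inp, pkey))
        graph.edges.add((pkey, out))


def classify_process(process: ProcessNode, graph: ExperimentGraph) -> ProcessCategory:
    """Bucket a process by what it consumes and produces."""
    def is_data(key):
        return key[0] == "data"

    ins_data = [is_data(k) for k in process.inputs]
    outs_data = [is_data(k) for k in process.outputs]
    if not any(ins_data) and not any(outs_data):
        return ProcessCategory.MATERIAL_TO_MATERIAL
    if not any(ins_data) and any(outs_data):
        return ProcessCategory.MATERIAL_TO_DATA
    if all(ins_data) and all(outs_data):
        return ProcessCategory.DATA_TO_DATA
    return ProcessCategory.MIXED


def merge_study_assay(
    study_graph: ExperimentGraph, assay_graphs: list[ExperimentGraph]
) -> ExperimentGraph:
    """Merge a study graph with its assay graphs on shared sample names.

    Sample nodes with equal keys unify, carrying the union of their
    characteristics; factor assignments concatenate with origins kept.
    An assay sample missing from the study table is kept with a warning.
    """
    merged = ExperimentGraph(
        materials={k: replace(v, characteristics=list(v.characteristics))
                   for k, v in study_graph.materials.items()},
        data=dict(study_graph.data),
        processes=dict(study_graph.processes),
        edges=set(study_graph.edges),
        factor_assignments=list(study_graph.factor_assignments),
        warnings=list(study_graph.warnings),
    )
    study_samples = {
        k for k in study_graph.materials if k[1] == MaterialType.SAMPLE.value
    }
    seen = {a.key() for a in merged.factor_assignments}
    for ag in assay_graphs:
        for key, node in ag.materials.items():
            if key[1] == MaterialType.SAMPLE.value and key not in study_samples:
                merged.warnings.append(
                    f"assay sample {node.name!r} does not appear in the study table"
                )
            existing = merged.materials.get(key)
            if existing is None:
                merged.materials[key] = replace(
                    node, characteristics=list(node.characteristics)
                )
            else:
                known = {c.key() for c in existing.characteristics}
                for attr in node.characteristics:
                    if attr.key() in known:
                        continue
                    clash = [
                        c for c in existing.characteristics
                        if c.qualifier == attr.qualifier
                    ]
                    if clash:
                        merged.warnings.append(
                            f"material {node.name!r}: conflicting values for "
                            f"characteristic {attr.qualifier!r}: "
                            f"{clash[0].value.text!r} vs {attr.value.text!r}"
                        )
                    existing.characteristics.append(attr)
                if node.declared_type_iri and not existing.declared_type_iri:
                    existing.declared_type_iri = node.declared_type_iri
        merged.data.update(ag.data)
        merged.processes.update(ag.processes)
        merged.edges.update(ag.edges)
        for fva in ag.factor_assignments:
            if fva.key() not in seen:
                seen.add(fva.key())
                merged.factor_assignments.append(fva)
        merged.warnings.extend(w for w in ag.warnings if w not in merged.warnings)
    merged.check_acyclic()
    return merged


def build_study_graph(study: Study, ontology_sources=None) -> ExperimentGraph:
    """Convenience: build and merge the study table graph with all of the
    study's assay table graphs."""
    if study.study_table is None:
        raise GraphStructureError(f"study {study.identifier!r} has no parsed table")
    sg = build_graph(study.study_table, study, TableContext.STUDY, ontology_sources)
    ags = [
        build_graph(a.assay_table, study, TableContext.ASSAY, ontology_sources)
        for a in study.assays
        if a.assay_table is not None
    ]
    return merge_study_assay(sg, ags)
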