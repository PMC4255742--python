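"""Conversion of the experiment graph plus investigation metadata to RDF.

Every individual gets an IRI minted under a user-supplied base IRI with
the pattern ``<base>/<type>/<counter>``, counters starting at 1 per type
and enumerating individuals in order of creation; an element is minted
at most once, so a sample shared by the study and an assay table is one
individual.  Classes and properties come from the loaded mapping set
(falling back to the configurable ISA vocabulary namespace), so the
same engine serves different semantic frameworks.

Beyond a one-to-one rendering of the tables, the converter adds what is
only implicit in ISA-Tab: study groups — one per distinct combination of
factor levels over the declared factors — with their sizes, and links
factor levels to their factors (never to samples, whose factor values
may legitimately live in either the study or the assay file).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS
from rdflib.term import Node

from . import vocab
from .errors import ConfigurationError, ValidationError
from .graph_analyser import (
    AttributeValue,
    DataKind,
    ExperimentGraph,
    MaterialType,
    build_study_graph,
)
from .isatab_io import Investigation, Study, parse_archive
from .semantic_mapping import (
    MappingSet,
    property_edges_for,
    resolve_property,
    resolve_type,
)

_MATERIAL_ELEMENT = {
    MaterialType.SOURCE: vocab.SOURCE_NAME,
    MaterialType.SAMPLE: vocab.SAMPLE_NAME,
    MaterialType.EXTRACT: vocab.EXTRACT_NAME,
    MaterialType.LABELED_EXTRACT: vocab.LABELED_EXTRACT_NAME,
    MaterialType.OTHER_MATERIAL: vocab.MATERIAL,
}

_DATA_ELEMENT = {
    DataKind.RAW: vocab.RAW_DATA_FILE,
    DataKind.DERIVED: vocab.DERIVED_DATA_FILE,
    DataKind.OTHER: vocab.DATA_FILE,
}


class IriPolicy:
    """Per-type counters under a base IRI; idempotent per element key."""

    def __init__(self, base_iri: str):
        if not base_iri.startswith(("http://", "https://", "urn:")):
            raise ConfigurationError(f"base IRI is not absolute: {base_iri!r}")
        self.base_iri = base_iri if base_iri.endswith("/") else base_iri + "/"
        self.counters: dict[str, int] = {}
        self._minted: dict[tuple, str] = {}

    def mint(self, type_name: str, element_key) -> str:
        type_name = type_name.strip().lower().replace(" ", "_")
        slot = (type_name, element_key)
        if slot in self._minted:
            return self._minted[slot]
        n = self.counters.get(type_name, 0) + 1
        self.counters[type_name] = n
        iri = f"{self.base_iri}{type_name}/{n}"
        self._minted[slot] = iri
        return iri

    def lookup(self, type_name: str, element_key) -> str | None:
        type_name = type_name.strip().lower().replace(" ", "_")
        return self._minted.get((type_name, element_key))


def mint_iri(policy: IriPolicy, type_name: str, element_key) -> str:
    return policy.mint(type_name, element_key)


class TripleSink:
    """A duplicate-free set of triples over an rdflib graph, plus the
    validation messages accumulated during conversion."""

    def __init__(self, named_graph: str | None = None):
        self.graph = Graph(identifier=URIRef(named_graph) if named_graph else None)
        self.named_graph = named_graph
        self.messages: list[str] = []

    @staticmethod
    def _term(value):
        if isinstance(value, Node):
            return value
        return URIRef(value)

    def add(self, s, p, o) -> None:
        self.graph.add((self._term(s), self._term(p), self._term(o)))

    def __len__(self) -> int:
        return len(self.graph)

    def __contains__(self, triple) -> bool:
        s, p, o = triple
        return (self._term(s), self._term(p), self._term(o)) in self.graph

    def serialize(self, destination=None, format: str = "turtle"):
        return self.graph.serialize(destination=destination, format=format)

    def canonical_ntriples(self) -> bytes:
        """Sorted N-Triples, byte-stable across runs (no blank nodes are
        ever emitted, so sorting is a full canonicalisation)."""
        data = self.graph.serialize(format="nt")
        lines = sorted(ln for ln in data.splitlines() if ln.strip())
        return ("\n".join(lines) + "\n").encode()


@dataclass
class StudyGroup:
    """One combination of factor levels with its member samples."""

    combination: tuple  # sorted ((factor_name, level_text), ...)
    members: set = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.members)

    def label(self) -> str:
        return ";".join(f"{f}={l}" for f, l in self.combination)


def infer_study_groups(graph: ExperimentGraph, study: Study) -> list[StudyGroup]:
    """Group samples by their complete factor-level vector.

    A sample's vector is the union of its factor-value assignments from
    study and assay origins; conflicting levels for one (sample, factor)
    raise :class:`ValidationError`.  Samples missing a level for any
    declared factor are excluded (and reported by the converter);
    with no declared factors the group list is empty.
    """
    declared = study.factor_names()
    if not declared:
        return []
    vectors: dict[tuple, dict[str, str]] = {}
    for fva in graph.factor_assignments:
        if fva.factor_name not in declared:
            continue
        vec = vectors.setdefault(fva.sample_key, {})
        prior = vec.get(fva.factor_name)
        if prior is not None and prior != fva.level.text:
            raise ValidationError(
                f"sample {fva.sample_key[2]!r}: conflicting levels for factor "
                f"{fva.factor_name!r}: {prior!r} vs {fva.level.text!r}"
            )
        vec[fva.factor_name] = fva.level.text
    groups: dict[tuple, StudyGroup] = {}
    for sample_key, vec in vectors.items():
        if set(vec) != set(declared):
            continue
        combo = tuple(sorted(vec.items()))
        groups.setdefault(combo, StudyGroup(combo)).members.add(sample_key)
    return [groups[c] for c in sorted(groups)]


def incomplete_samples(graph: ExperimentGraph, study: Study) -> list[tuple]:
    """Sample keys with a partial factor vector (assigned some but not
    all declared factors)."""
    declared = set(study.factor_names())
    if not declared:
        return []
    vectors: dict[tuple, set] = {}
    for fva in graph.factor_assignments:
        if fva.factor_name in declared:
            vectors.setdefault(fva.sample_key, set()).add(fva.factor_name)
    return sorted(k for k, assigned in vectors.items() if assigned != declared)


def convert(
    investigation: Investigation,
    graphs: dict[str, ExperimentGraph] | ExperimentGraph | None,
    mappings: MappingSet,
    policy: IriPolicy,
    named_graph: str | None = None,
) -> TripleSink:
    """Convert an investigation and its experiment graph(s) to RDF.

    ``graphs`` maps study identifiers to merged experiment graphs; a
    single graph is taken as belonging to the first study, and ``None``
    builds the graphs from the parsed tables.
    """
    if graphs is None:
        graphs = {
            s.identifier: build_study_graph(s, investigation.ontology_sources)
            for s in investigation.studies
        }
    elif isinstance(graphs, ExperimentGraph):
        graphs = {investigation.studies[0].identifier: graphs}

    sink = TripleSink(named_graph)
    prop = lambda name: resolve_property(name, mappings)  # noqa: E731
    rdf_type = RDF.type

    dataset_iri = policy.mint("isa_dataset", ("investigation", investigation.identifier))
    sink.add(dataset_iri, rdf_type, resolve_type(vocab.INVESTIGATION, None, mappings))
    if investigation.identifier:
        sink.add(dataset_iri, prop(vocab.IDENTIFIER), Literal(investigation.identifier))
    if investigation.title:
        sink.add(dataset_iri, RDFS.label, Literal(investigation.title))

    for study in investigation.studies:
        graph = graphs.get(study.identifier)
        _convert_study(sink, dataset_iri, investigation, study, graph, mappings, policy)
    return sink


def _convert_study(sink, dataset_iri, investigation, study, graph, mappings, policy):
    prop = lambda name: resolve_property(name, mappings)  # noqa: E731
    skey = ("study", study.identifier)
    study_iri = policy.mint("study", skey)
    sink.add(study_iri, RDF.type, resolve_type(vocab.STUDY, None, mappings))
    sink.add(dataset_iri, prop(vocab.HAS_PART), study_iri)
    if study.identifier:
        sink.add(study_iri, prop(vocab.IDENTIFIER), Literal(study.identifier))
    if study.title:
        sink.add(study_iri, RDFS.label, Literal(study.title))

    design_iri = policy.mint("study_design", skey + ("design",))
    sink.add(design_iri, RDF.type, resolve_type(vocab.STUDY_DESIGN, None, mappings))
    sink.add(study_iri, prop(vocab.HAS_DESIGN), design_iri)
    for descriptor in study.design_descriptors:
        if descriptor.resolved_iri:
            sink.add(design_iri, RDF.type, descriptor.resolved_iri)
        if descriptor.text:
            sink.add(design_iri, RDFS.label, Literal(descriptor.text))

    factor_iris: dict[str, str] = {}
    for factor in study.factors:
        firi = policy.mint("study_factor", skey + ("factor", factor.name))
        factor_iris[factor.name] = firi
        sink.add(firi, RDF.type, resolve_type(vocab.STUDY_FACTOR, None, mappings))
        if factor.type.resolved_iri:
            sink.add(firi, RDF.type, factor.type.resolved_iri)
        sink.add(firi, RDFS.label, Literal(factor.name))
        sink.add(study_iri, prop(vocab.HAS_FACTOR), firi)

    protocol_iris: dict[str, str] = {}
    for protocol in study.protocols:
        piri = policy.mint("study_protocol", skey + ("protocol", protocol.name))
        protocol_iris[protocol.name] = piri
        sink.add(piri, RDF.type, resolve_type(vocab.STUDY_PROTOCOL, None, mappings))
        if protocol.type.resolved_iri:
            sink.add(piri, RDF.type, protocol.type.resolved_iri)
        sink.add(piri, RDFS.label, Literal(protocol.name))
        sink.add(study_iri, prop(vocab.HAS_PROTOCOL), piri)

    for assay in study.assays:
        airi = policy.mint("assay", skey + ("assay", assay.file_name))
        sink.add(airi, RDF.type, resolve_type(vocab.STUDY_ASSAY, None, mappings))
        label = " ".join(t for t in (assay.measurement.text, assay.technology.text) if t)
        sink.add(airi, RDFS.label, Literal(label or assay.file_name))
        if assay.measurement.resolved_iri:
            sink.add(airi, RDF.type, assay.measurement.resolved_iri)
        sink.add(study_iri, prop(vocab.HAS_ASSAY), airi)

    if graph is None:
        return
    sink.messages.extend(graph.warnings)

    node_iris: dict[tuple, str] = {}
    for key, node in graph.materials.items():
        element = _MATERIAL_ELEMENT[node.node_type]
        iri = policy.mint(node.node_type.value, key)
        node_iris[key] = iri
        sink.add(iri, RDF.type, resolve_type(element, None, mappings))
        if node.declared_type_iri:
            sink.add(iri, RDF.type, node.declared_type_iri)
        sink.add(iri, RDFS.label, Literal(node.name))
        emit_attributes(
            iri, node.characteristics, mappings, sink,
            policy=policy, link=vocab.HAS_CHARACTERISTIC,
            value_type="characteristic_value", owner_key=key,
        )
    for key, node in graph.data.items():
        iri = policy.mint("data_file", key)
        node_iris[key] = iri
        sink.add(iri, RDF.type, resolve_type(_DATA_ELEMENT[node.data_kind], None, mappings))
        sink.add(iri, RDFS.label, Literal(node.name))

    for key, process in graph.processes.items():
        context = process.context
        iri = policy.mint("process", key)
        sink.add(iri, RDF.type, resolve_type(vocab.PROTOCOL_REF, context, mappings))
        sink.add(iri, RDFS.label, Literal(process.protocol_name))
        if process.protocol_name in protocol_iris:
            sink.add(iri, prop(vocab.EXECUTES_PROTOCOL), protocol_iris[process.protocol_name])
        for in_key in process.inputs:
            if in_key in node_iris:
                sink.add(iri, prop(vocab.HAS_INPUT), node_iris[in_key])
        for out_key in process.outputs:
            if out_key in node_iris:
                sink.add(iri, prop(vocab.HAS_OUTPUT), node_iris[out_key])
        emit_attributes(
            iri, process.parameter_values, mappings, sink,
            policy=policy, link=vocab.HAS_PARAMETER_VALUE,
            value_type="parameter_value", owner_key=key,
        )

    # factor levels attach to factors, never to samples
    level_iris: dict[tuple[str, str], str] = {}
    declared = study.factor_names()
    level_annotations: dict[tuple[str, str], str] = {}
    for fva in graph.factor_assignments:
        if fva.factor_name in declared:
            level_annotations.setdefault(
                (fva.factor_name, fva.level.text), fva.level.resolved_iri
            )
    for factor_name in declared:
        levels = sorted(t for f, t in level_annotations if f == factor_name)
        for text in levels:
            liri = policy.mint("factor_level", skey + ("level", factor_name, text))
            level_iris[(factor_name, text)] = liri
            sink.add(liri, RDF.type, resolve_type(vocab.FACTOR_VALUE_ELEMENT, None, mappings))
            term = level_annotations[(factor_name, text)]
            if term:
                sink.add(liri, RDF.type, term)
            sink.add(liri, RDFS.label, Literal(text))
            sink.add(factor_iris[factor_name], prop(vocab.HAS_LEVEL), liri)

    for omitted in incomplete_samples(graph, study):
        sink.messages.append(
            f"sample {omitted[2]!r} has a partial factor vector and is "
            "excluded from study groups"
        )
    for group in infer_study_groups(graph, study):
        giri = policy.mint("study_group", skey + ("group",) + group.combination)
        sink.add(giri, RDF.type, resolve_type(vocab.STUDY_GROUP, None, mappings))
        sink.add(giri, RDFS.label, Literal(group.label()))
        sink.add(study_iri, prop(vocab.HAS_GROUP), giri)
        sink.add(giri, prop(vocab.HAS_SIZE), Literal(group.size))
        for factor_name, text in group.combination:
            sink.add(giri, prop(vocab.HAS_LEVEL), level_iris[(factor_name, text)])
        for member in sorted(group.members):
            if member in node_iris:
                sink.add(giri, prop(vocab.HAS_MEMBER), node_iris[member])


def emit_attributes(
    node_iri: str,
    attributes: list[AttributeValue],
    mappings: MappingSet,
    sink: TripleSink,
    *,
    policy: IriPolicy,
    link: str = vocab.HAS_CHARACTERISTIC,
    value_type: str = "characteristic_value",
    owner_key=None,
) -> None:
    """Emit one attribute (characteristic / parameter value) of a node.

    A value whose term resolves, or whose category resolves through the
    mapping set, becomes an individual typed accordingly; otherwise the
    bearer gets a plain literal.  Property rows matching the attribute's
    element form add specific edges between sibling value individuals
    (e.g. a tissue value is part of the organism value on the same node).
    """
    link_iri = resolve_property(link, mappings)
    value_iris: dict[str, str] = {}  # element form -> value individual
    materialised: list[tuple[AttributeValue, str]] = []
    for attr in attributes:
        if attr.value.is_empty():
            continue
        category = mappings.lookup_type(attr.element_form)
        edges = property_edges_for(attr.element_form, mappings)
        class_iri = category.class_iri if category is not None else ""
        if not class_iri:
            for edge in edges:
                if edge.subject_class_iri:
                    class_iri = edge.subject_class_iri
                    break
        if not (class_iri or attr.value.resolved_iri or edges
                or _is_property_object(attr.element_form, mappings)):
            sink.add(node_iri, link_iri, Literal(attr.value.text))
            continue
        viri = policy.mint(value_type, (owner_key, attr.key()))
        value_iris[attr.element_form] = viri
        materialised.append((attr, viri))
        sink.add(node_iri, link_iri, viri)
        if class_iri:
            sink.add(viri, RDF.type, class_iri)
        if attr.value.resolved_iri:
            sink.add(viri, RDF.type, attr.value.resolved_iri)
        sink.add(viri, RDFS.label, Literal(attr.value.text))
        if attr.unit is not None:
            unit_iri = resolve_property(vocab.HAS_UNIT, mappings)
            if attr.unit.resolved_iri:
                sink.add(viri, unit_iri, attr.unit.resolved_iri)
            else:
                sink.add(viri, unit_iri, Literal(attr.unit.text))
    for attr, viri in materialised:
        for edge in property_edges_for(attr.element_form, mappings):
            if edge.object_element and edge.object_element in value_iris:
                sink.add(viri, edge.property_iri, value_iris[edge.object_element])
            elif edge.object_element:
                sink.messages.append(
                    f"property mapping for {attr.element_form!r}: no sibling "
                    f"value for {edge.object_element!r}; edge skipped"
                )
            else:
                sink.add(viri, edge.property_iri, edge.object_iri)


def _is_property_object(element_form: str, mappings: MappingSet) -> bool:
    """True when some property row references this element as its object
    (such a value must be materialised to serve as the edge target)."""
    from .semantic_mapping import PropertyMapping

    return any(
        isinstance(m, PropertyMapping) and m.object_element == element_form
        for file in mappings.files
        for m in file
    )


def convert_archive(
    path: Path | str,
    base_iri: str,
    mappings: MappingSet | None = None,
    framework: str | None = "obi",
    extra_mapping_files=(),
    named_graph: str | None = None,
) -> TripleSink:
    """Parse an archive, recover its graphs, and convert to RDF."""
    if mappings is None:
        mappings = MappingSet.load(framework, extra_mapping_files)
    investigation = parse_archive(path)
    policy = IriPolicy(base_iri)
    return convert(investigation, None, mappings, policy, named_graph)
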