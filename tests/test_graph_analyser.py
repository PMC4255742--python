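"""DAG recovery: segmentation, identity, classification, merging."""

import itertools

import pytest

from isardf.errors import GraphStructureError
from isardf.graph_analyser import (
    MaterialType,
    ProcessCategory,
    build_graph,
    build_study_graph,
    merge_study_assay,
)
from isardf.isatab_io import (
    DATA_KINDS,
    MATERIAL_KINDS,
    Study,
    TableContext,
    parse_archive,
    parse_table_file,
)
from .conftest import write_table


def table(tmp_path, headers, rows, name="s_t.txt", context=TableContext.STUDY):
    p = tmp_path / name
    write_table(p, headers, rows)
    return parse_table_file(p, context)


def study_decl(factors=(), protocols=("growth",)):
    from isardf.isatab_io import FactorDefinition, ProtocolDefinition

    return Study(
        identifier="S",
        factors=[FactorDefinition(f) for f in factors],
        protocols=[ProtocolDefinition(p) for p in protocols],
    )


def test_minimal_chain(tmp_path):
    t = table(tmp_path, ["Source Name", "Protocol REF", "Sample Name"],
              [["src1", "growth", "sam1"]])
    g = build_graph(t, study_decl(), TableContext.STUDY)
    assert len(g.materials) == 2
    assert len(g.processes) == 1
    proc = next(iter(g.processes.values()))
    assert proc.inputs == [("material", "source", "src1")]
    assert proc.outputs == [("material", "sample", "sam1")]
    assert len(g.edges) == 2


def test_same_protocol_different_inputs_stays_distinct(tmp_path):
    t = table(tmp_path, ["Source Name", "Protocol REF", "Sample Name"],
              [["src1", "growth", "sam1"], ["src2", "growth", "sam1"]])
    g = build_graph(t, study_decl(), TableContext.STUDY)
    assert len(g.materials) == 3
    assert len(g.processes) == 2  # different inputs => different applications


def test_identical_rows_merge(tmp_path):
    t = table(tmp_path, ["Source Name", "Protocol REF", "Sample Name"],
              [["src1", "growth", "sam1"], ["src1", "growth", "sam1"]])
    g = build_graph(t, study_decl(), TableContext.STUDY)
    assert len(g.processes) == 1


def test_parameter_value_splits_identity(tmp_path):
    t = table(
        tmp_path,
        ["Sample Name", "Protocol REF", "Parameter Value[temp]", "Extract Name"],
        [["sam1", "extraction", "4C", "e1"], ["sam2", "extraction", "37C", "e2"],
         ["sam3", "extraction", "4C", "e3"]],
        context=TableContext.ASSAY,
    )
    g = build_graph(t, study_decl(protocols=("extraction",)), TableContext.ASSAY)
    temps = {
        frozenset(pv.value.text for pv in p.parameter_values)
        for p in g.processes.values()
    }
    assert len(g.processes) == 3
    assert temps == {frozenset({"4C"}), frozenset({"37C"})}


def test_process_categories_along_assay_chain(tmp_path):
    t = table(
        tmp_path,
        ["Sample Name", "Protocol REF", "Extract Name", "Protocol REF",
         "Labeled Extract Name", "Protocol REF", "Raw Data File"],
        [["sam1", "extraction", "e1", "labeling", "l1", "hybridization", "d1.raw"]],
        context=TableContext.ASSAY,
    )
    g = build_graph(
        t, study_decl(protocols=("extraction", "labeling", "hybridization")),
        TableContext.ASSAY,
    )
    cats = [p.category for p in g.processes.values()]
    assert sorted(c.value for c in cats) == sorted(
        [ProcessCategory.MATERIAL_TO_MATERIAL.value,
         ProcessCategory.MATERIAL_TO_MATERIAL.value,
         ProcessCategory.MATERIAL_TO_DATA.value]
    )


def test_data_to_data_category(tmp_path):
    t = table(tmp_path, ["Raw Data File", "Protocol REF", "Derived Data File"],
              [["r1", "normalize", "d1"]], context=TableContext.ASSAY)
    g = build_graph(t, study_decl(protocols=("normalize",)), TableContext.ASSAY)
    assert [p.category for p in g.processes.values()] == [ProcessCategory.DATA_TO_DATA]


def test_consecutive_protocol_refs_chain_via_intermediates(tmp_path):
    t = table(
        tmp_path,
        ["Source Name", "Protocol REF", "Protocol REF", "Sample Name"],
        [["src1", "treat", "wash", "sam1"]],
    )
    g = build_graph(t, study_decl(protocols=("treat", "wash")), TableContext.STUDY)
    assert len(g.processes) == 2
    anon = [m for m in g.materials.values() if m.node_type is MaterialType.OTHER_MATERIAL]
    assert len(anon) == 1  # minted intermediate between the two applications


def test_empty_output_cell_attaches_to_next_node(tmp_path):
    t = table(
        tmp_path,
        ["Source Name", "Protocol REF", "Sample Name", "Protocol REF", "Extract Name"],
        [["src1", "growth", "", "extraction", "e1"]],
    )
    g = build_graph(t, study_decl(protocols=("growth", "extraction")), TableContext.STUDY)
    # with sam cell empty the two protocols form one chained run src1 -> e1
    assert len(g.processes) == 2
    ins = {p.protocol_name: p.inputs[0] for p in g.processes.values()}
    assert ins["growth"] == ("material", "source", "src1")


def test_characteristics_attach_left_and_multivalue_warns(tmp_path):
    t = table(
        tmp_path,
        ["Source Name", "Characteristics[OBI:organism]", "Term Source REF",
         "Term Accession Number", "Protocol REF", "Sample Name"],
        [["src1", "Homo sapiens", "NCBItaxon", "9606", "growth", "sam1"],
         ["src1", "Mus musculus", "NCBItaxon", "10090", "growth", "sam2"]],
    )
    from isardf.isatab_io import OntologySourceRef

    sources = [OntologySourceRef("NCBItaxon", "http://purl.obolibrary.org/obo/NCBITaxon_")]
    g = build_graph(t, study_decl(), TableContext.STUDY, sources)
    src = g.materials[("material", "source", "src1")]
    assert len(src.characteristics) == 2  # both values kept
    assert any("multiple values" in w for w in g.warnings)
    assert src.characteristics[0].value.resolved_iri.endswith("NCBITaxon_9606")


def test_undeclared_protocol_and_factor_warn(tmp_path):
    t = table(
        tmp_path,
        ["Source Name", "Protocol REF", "Sample Name", "Factor Value[dose]"],
        [["src1", "mystery", "sam1", "low"]],
    )
    g = build_graph(t, study_decl(factors=("other",)), TableContext.STUDY)
    assert any("mystery" in w for w in g.warnings)
    assert any("dose" in w for w in g.warnings)
    assert len(g.factor_assignments) == 1  # kept despite the warning


def test_cycle_is_rejected(tmp_path):
    t = table(
        tmp_path,
        ["Sample Name", "Protocol REF", "Sample Name"],
        [["s1", "p", "s2"], ["s2", "p", "s1"]],
    )
    with pytest.raises(GraphStructureError):
        build_graph(t, study_decl(protocols=("p",)), TableContext.STUDY)


def test_merge_unifies_samples_and_warns_on_dangling(tmp_path):
    st = table(tmp_path, ["Source Name", "Protocol REF", "Sample Name"],
               [[f"src{i}", "growth", f"sam{i}"] for i in range(1, 5)], name="s_a.txt")
    at = table(tmp_path, ["Sample Name", "Protocol REF", "Raw Data File"],
               [["sam1", "scan", "d1"], ["sam2", "scan", "d2"]],
               name="a_a.txt", context=TableContext.ASSAY)
    decl = study_decl(protocols=("growth", "scan"))
    sg = build_graph(st, decl, TableContext.STUDY)
    ag = build_graph(at, decl, TableContext.ASSAY)
    merged = merge_study_assay(sg, [ag])
    samples = [k for k in merged.materials if k[1] == "sample"]
    assert len(samples) == 4

    at2 = table(tmp_path, ["Sample Name", "Protocol REF", "Raw Data File"],
                [["sam9", "scan", "d9"]], name="a_b.txt", context=TableContext.ASSAY)
    ag2 = build_graph(at2, decl, TableContext.ASSAY)
    merged2 = merge_study_assay(sg, [ag, ag2])
    assert any("sam9" in w for w in merged2.warnings)
    assert len([k for k in merged2.materials if k[1] == "sample"]) == 5


def test_merge_order_independent(crossed_archive):
    path, _ = crossed_archive
    inv = parse_archive(path)
    study = inv.studies[0]
    sg = build_graph(study.study_table, study, TableContext.STUDY, inv.ontology_sources)
    # split the assay rows into overlapping halves to get several graphs
    from dataclasses import replace

    at = study.assays[0].assay_table
    half = len(at.rows) // 2
    parts = [
        replace(at, rows=at.rows[:half]),
        replace(at, rows=at.rows[half:]),
        replace(at, rows=at.rows[::2]),
    ]
    ags = [
        build_graph(p, study, TableContext.ASSAY, inv.ontology_sources) for p in parts
    ]
    keysets = set()
    for perm in itertools.permutations(ags):
        m = merge_study_assay(sg, list(perm))
        keysets.add(
            frozenset(m.materials) | frozenset(m.data) | frozenset(m.processes)
        )
    assert len(keysets) == 1


def brute_force_node_count(inv):
    """Distinct (kind, name) pairs over all node columns of all tables."""
    names = set()
    for study in inv.studies:
        tables = [study.study_table] + [a.assay_table for a in study.assays]
        for t in tables:
            for h in t.headers:
                if h.kind in MATERIAL_KINDS or h.kind in DATA_KINDS:
                    for row in t.rows:
                        if row[h.position]:
                            names.add((h.kind, row[h.position]))
    return len(names)


def test_node_conservation_against_brute_force(crossed_archive):
    path, _ = crossed_archive
    inv = parse_archive(path)
    g = build_study_graph(inv.studies[0], inv.ontology_sources)
    named = [k for k in list(g.materials) + list(g.data) if not k[2].startswith("_intermediate")]
    assert len(named) == brute_force_node_count(inv)


def test_edges_are_bipartite(simple_archive):
    path, _ = simple_archive
    inv = parse_archive(path)
    g = build_study_graph(inv.studies[0], inv.ontology_sources)
    for a, b in g.edges:
        assert (a[0] == "process") != (b[0] == "process")
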