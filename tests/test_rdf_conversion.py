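"""IRI minting, triple emission, study-group inference."""

import pytest
from rdflib import Literal, URIRef
from rdflib.namespace import RDF

from isardf.errors import ConfigurationError, ValidationError
from isardf.fixtures import FixtureSpec, generate_fixture
from isardf.graph_analyser import build_graph, build_study_graph
from isardf.isatab_io import TableContext, parse_archive, parse_table_file
from isardf.rdf_conversion import IriPolicy, convert, infer_study_groups, mint_iri
from isardf.semantic_mapping import MappingSet
from isardf.vocab import ISA_TERMS
from .conftest import BASE, TISSUE_MAPPING_LINE, convert_path, write_table

OBO = "http://purl.obolibrary.org/obo/"


class TestIriPolicy:
    def test_pattern_and_counter_start(self):
        policy = IriPolicy("http://w3id.org/isa/soapdenovo2/")
        iri = mint_iri(policy, "isa_dataset", ("investigation", "sd2"))
        assert iri == "http://w3id.org/isa/soapdenovo2/isa_dataset/1"

    def test_counter_increments_per_type(self):
        policy = IriPolicy("http://w3id.org/isa/soapdenovo2/")
        mint_iri(policy, "isa_dataset", ("investigation", "a"))
        assert mint_iri(policy, "isa_dataset", ("investigation", "b")).endswith(
            "/isa_dataset/2"
        )
        assert mint_iri(policy, "sample", ("material", "sample", "x")).endswith(
            "/sample/1"
        )

    def test_idempotent_per_element(self):
        policy = IriPolicy("http://example.org/x")  # slash appended
        a = mint_iri(policy, "sample", ("material", "sample", "x"))
        b = mint_iri(policy, "sample", ("material", "sample", "x"))
        assert a == b == "http://example.org/x/sample/1"

    def test_non_absolute_base_rejected(self):
        with pytest.raises(ConfigurationError):
            IriPolicy("relative/base/")


def test_organism_annotation_types_the_source(simple_rdf):
    sink, _ = simple_rdf
    g = sink.graph
    taxon = URIRef(OBO + "NCBITaxon_9606")
    sources = {
        s for s in g.subjects(RDF.type, URIRef(ISA_TERMS + "Source"))
    }
    typed = set(g.subjects(RDF.type, taxon))
    assert sources and sources <= typed


def test_organism_category_class(simple_rdf):
    sink, truth = simple_rdf
    n = len(set(sink.graph.subjects(RDF.type, URIRef(OBO + "OBI_0100026"))))
    assert n == truth.studies["study01"].n_samples  # one value individual per source


def test_contextual_process_typing(simple_rdf):
    sink, truth = simple_rdf
    g = sink.graph
    n = truth.studies["study01"].n_samples
    study_procs = set(g.subjects(RDF.type, URIRef(OBO + "OBI_0000094")))
    assay_procs = set(g.subjects(RDF.type, URIRef(OBO + "OBI_0000011")))
    assert len(study_procs) == n  # one collection per sample
    assert len(assay_procs) == 3 * n  # three chain steps per sample
    assert not study_procs & assay_procs


def test_sample_is_one_individual_across_tables(simple_rdf):
    sink, truth = simple_rdf
    samples = set(
        sink.graph.subjects(RDF.type, URIRef(OBO + "OBI_0100051"))
    )
    assert len(samples) == truth.studies["study01"].n_samples


def test_study_assay_typed_obi(simple_rdf):
    sink, _ = simple_rdf
    assert len(set(sink.graph.subjects(RDF.type, URIRef(OBO + "OBI_0000070")))) == 1


def test_determinism_byte_identical(simple_archive, obi_mappings):
    path, _ = simple_archive
    a = convert_path(path, obi_mappings).canonical_ntriples()
    b = convert_path(path, obi_mappings).canonical_ntriples()
    assert a == b


def _skeleton(sink):
    """Triples with minted IRIs reduced to their type segment, an
    identity-preserving view invariant under row permutation."""
    def squash(term):
        s = str(term)
        if s.startswith(BASE):
            return "minted:" + s[len(BASE):].rsplit("/", 1)[0]
        return s

    return sorted((squash(s), squash(p), squash(o)) for s, p, o in sink.graph)


def test_row_permutation_invariance(tmp_path, obi_mappings):
    spec = FixtureSpec(factors=[("dose", ["low", "high"])], group_size=2, seed=21)
    generate_fixture(spec, tmp_path / "a")
    a = convert_path(tmp_path / "a", obi_mappings)

    # reverse the data rows of every table file
    import shutil

    shutil.copytree(tmp_path / "a", tmp_path / "b")
    for f in (tmp_path / "b").glob("[sa]_*.txt"):
        lines = f.read_text(encoding="utf-8").splitlines()
        f.write_text("\n".join([lines[0]] + lines[:0:-1]) + "\n", encoding="utf-8")
    b = convert_path(tmp_path / "b", obi_mappings)
    assert len(a) == len(b)
    assert _skeleton(a) == _skeleton(b)


def test_no_sample_to_factor_value_triple(crossed_rdf):
    sink, _ = crossed_rdf
    g = sink.graph
    samples = set(g.subjects(RDF.type, URIRef(OBO + "OBI_0100051")))
    levels = set(g.subjects(RDF.type, URIRef(ISA_TERMS + "FactorValue")))
    assert samples and levels
    assert not [(s, p, o) for s, p, o in g if s in samples and o in levels]
    # but factor -> level links exist
    has_level = URIRef(ISA_TERMS + "hasLevel")
    factors = set(g.subjects(RDF.type, URIRef(ISA_TERMS + "StudyFactor")))
    assert any(s in factors for s, o in g.subject_objects(has_level))


def test_iri_uniqueness(crossed_archive, obi_mappings):
    path, _ = crossed_archive
    inv = parse_archive(path)
    graphs = {
        s.identifier: build_study_graph(s, inv.ontology_sources) for s in inv.studies
    }
    policy = IriPolicy(BASE)
    convert(inv, graphs, obi_mappings, policy)
    iris = list(policy._minted.values())
    assert len(iris) == len(set(iris))


class TestStudyGroups:
    def make(self, tmp_path, sizes, obi_mappings):
        spec = FixtureSpec(factors=[("dose", ["low", "high"])], group_size=sizes, seed=9)
        generate_fixture(spec, tmp_path / "g")
        inv = parse_archive(tmp_path / "g")
        study = inv.studies[0]
        return study, build_study_graph(study, inv.ontology_sources)

    def test_direct_grouping(self, tmp_path, obi_mappings):
        study, graph = self.make(tmp_path, 2, obi_mappings)
        groups = infer_study_groups(graph, study)
        assert [g.size for g in groups] == [2, 2]
        assert groups[0].combination == (("dose", "high"),)

    def test_partition_property(self, crossed_archive):
        path, truth = crossed_archive
        inv = parse_archive(path)
        study = inv.studies[0]
        graph = build_study_graph(study, inv.ontology_sources)
        groups = infer_study_groups(graph, study)
        members = [g.members for g in groups]
        assert sum(len(m) for m in members) == truth.studies["study01"].n_samples
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                assert not a & b

    def test_no_declared_factors_no_groups(self, tmp_path):
        write_table(tmp_path / "s_x.txt",
                    ["Source Name", "Protocol REF", "Sample Name"],
                    [["src1", "growth", "sam1"]])
        from .test_graph_analyser import study_decl

        t = parse_table_file(tmp_path / "s_x.txt", TableContext.STUDY)
        study = study_decl()
        graph = build_graph(t, study, TableContext.STUDY)
        assert infer_study_groups(graph, study) == []

    def test_conflicting_levels_error(self, tmp_path):
        spec = FixtureSpec(
            factors=[("dose", ["low", "high"])], group_size=2, seed=2,
            factor_values_in="both",
        )
        generate_fixture(spec, tmp_path / "c")
        # flip one assay-level factor value so study and assay disagree
        afile = next((tmp_path / "c").glob("a_*.txt"))
        lines = afile.read_text(encoding="utf-8").splitlines()
        for i in range(1, len(lines)):
            if lines[i].endswith("\tlow"):
                lines[i] = lines[i][: -len("low")] + "high"
                break
        afile.write_text("\n".join(lines) + "\n", encoding="utf-8")
        inv = parse_archive(tmp_path / "c")
        study = inv.studies[0]
        graph = build_study_graph(study, inv.ontology_sources)
        with pytest.raises(ValidationError, match="conflicting levels"):
            infer_study_groups(graph, study)


def test_tissue_extension_mapping_adds_part_of_edge(tmp_path, obi_mappings):
    write_table(
        tmp_path / "s_s1.txt",
        ["Source Name", "Characteristics[OBI:organism]", "Term Source REF",
         "Term Accession Number", "Characteristics[OBI:tissue specimen]",
         "Protocol REF", "Sample Name"],
        [["src1", "Homo sapiens", "NCBItaxon", "9606", "liver", "collect", "sam1"]],
    )
    (tmp_path / "i_investigation.txt").write_text(
        "ONTOLOGY SOURCE REFERENCE\n"
        "Term Source Name\tNCBItaxon\n"
        "Term Source File\thttp://purl.obolibrary.org/obo/NCBITaxon_\n"
        "INVESTIGATION\nInvestigation Identifier\tinv-t\n"
        "STUDY\nStudy Identifier\ts1\nStudy Title\tt\nStudy File Name\ts_s1.txt\n"
        "STUDY PROTOCOLS\nStudy Protocol Name\tcollect\n",
        encoding="utf-8",
    )
    mfile = tmp_path / "tissue.csv"
    mfile.write_text(TISSUE_MAPPING_LINE + "\n", encoding="utf-8")
    ms = MappingSet.load("obi", [mfile])
    sink = convert_path(tmp_path, ms)
    part_of = URIRef(OBO + "BFO_0000050")
    pairs = list(sink.graph.subject_objects(part_of))
    assert len(pairs) == 1
    tissue_value, organism_value = pairs[0]
    assert (organism_value, RDF.type, URIRef(OBO + "OBI_0100026")) in sink.graph
    assert (tissue_value, RDF.type, URIRef(OBO + "OBI_0001479")) in sink.graph


def test_unmapped_literal_characteristic_stays_literal(tmp_path, obi_mappings):
    write_table(
        tmp_path / "s_s1.txt",
        ["Source Name", "Characteristics[colour]", "Protocol REF", "Sample Name"],
        [["src1", "green", "collect", "sam1"]],
    )
    (tmp_path / "i_investigation.txt").write_text(
        "INVESTIGATION\nInvestigation Identifier\tinv-l\n"
        "STUDY\nStudy Identifier\ts1\nStudy File Name\ts_s1.txt\n"
        "STUDY PROTOCOLS\nStudy Protocol Name\tcollect\n",
        encoding="utf-8",
    )
    sink = convert_path(tmp_path, obi_mappings)
    has_char = URIRef(ISA_TERMS + "hasCharacteristic")
    objs = list(sink.graph.objects(None, has_char))
    assert objs == [Literal("green")]
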