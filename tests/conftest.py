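"""Shared fixtures: synthetic archives, mapping sets, converted graphs."""

from __future__ import annotations

import pytest

from isardf.fixtures import FixtureSpec, generate_fixture
from isardf.rdf_conversion import IriPolicy, convert
from isardf.isatab_io import parse_archive
from isardf.graph_analyser import build_study_graph
from isardf.semantic_mapping import MappingSet

BASE = "http://example.org/conv/"

#: a tissue-extension property-mapping line (comma-delimited)
TISSUE_MAPPING_LINE = (
    "Characteristics[OBI:tissue specimen],tissue,"
    "http://purl.obolibrary.org/obo/OBI_0001479, is part of, "
    "http://purl.obolibrary.org/obo/BFO_0000050, organism, "
    "Characteristics[OBI:organism]"
)


@pytest.fixture(scope="session")
def obi_mappings() -> MappingSet:
    return MappingSet.load("obi")


@pytest.fixture
def simple_archive(tmp_path):
    """One study, factor dose {low, high}, 3 samples per level."""
    spec = FixtureSpec(factors=[("dose", ["low", "high"])], group_size=3, seed=1)
    truth = generate_fixture(spec, tmp_path / "arch")
    return tmp_path / "arch", truth


@pytest.fixture
def crossed_archive(tmp_path):
    """3x2 factorial design, 5 samples per cell (30 samples)."""
    spec = FixtureSpec(
        factors=[("agent", ["a", "b", "c"]), ("dose", ["low", "high"])],
        group_size=5,
        seed=11,
    )
    truth = generate_fixture(spec, tmp_path / "arch")
    return tmp_path / "arch", truth


@pytest.fixture
def imbalanced_archive(tmp_path):
    """One 2-level factor with group sizes {5, 4}."""
    spec = FixtureSpec(factors=[("dose", ["low", "high"])], group_size=[5, 4], seed=3)
    truth = generate_fixture(spec, tmp_path / "arch")
    return tmp_path / "arch", truth


def convert_path(path, mappings, base=BASE):
    inv = parse_archive(path)
    graphs = {
        s.identifier: build_study_graph(s, inv.ontology_sources) for s in inv.studies
    }
    return convert(inv, graphs, mappings, IriPolicy(base))


@pytest.fixture
def simple_rdf(simple_archive, obi_mappings):
    path, truth = simple_archive
    return convert_path(path, obi_mappings), truth


@pytest.fixture
def crossed_rdf(crossed_archive, obi_mappings):
    path, truth = crossed_archive
    return convert_path(path, obi_mappings), truth


@pytest.fixture
def imbalanced_rdf(imbalanced_archive, obi_mappings):
    path, truth = imbalanced_archive
    return convert_path(path, obi_mappings), truth


def write_table(path, header_lines, rows):
    lines = ["\t".join(header_lines)] + ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
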