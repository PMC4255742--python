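"""Study-design interrogation over the converted RDF.

Six SPARQL queries (shipped as ``.rq`` files so they can be diffed or
replaced) recover what ISA-Tab keeps implicit: factors and their levels,
level counts, study-group combinations with sizes, minimum/maximum group
size, the balanced/imbalanced verdict, and — the only write operation —
a CONSTRUCT that annotates the design individual of every balanced study
with a balanced-design class.  The annotation step also flags studies
previously annotated balanced whose recomputed sizes disagree, instead
of silently retracting anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from rdflib import URIRef
from rdflib.plugins.sparql import prepareQuery

from .errors import ConfigurationError
from .rdf_conversion import TripleSink
from .semantic_mapping import MappingSet
from .vocab import BALANCED_DESIGN

_QUERY_CACHE: dict[str, object] = {}


def load_query(name: str) -> str:
    """Raw text of a shipped query file (e.g. ``factors_levels``)."""
    return resources.files("isardf.queries").joinpath(f"{name}.rq").read_text(
        encoding="utf-8"
    )


def _prepared(name: str):
    if name not in _QUERY_CACHE:
        _QUERY_CACHE[name] = prepareQuery(load_query(name))
    return _QUERY_CACHE[name]


def _run(sink: TripleSink, name: str):
    return sink.graph.query(_prepared(name))


def q_factors_levels(rdf: TripleSink) -> list[tuple[str, str, str]]:
    """Rows (study, factor, level), lexicographically ordered."""
    return sorted(
        (str(r.study), str(r.factor), str(r.level)) for r in _run(rdf, "factors_levels")
    )


def q_count_levels(rdf: TripleSink) -> list[tuple[str, str, int]]:
    """Rows (study, factor, number of distinct levels); factors with no
    assigned level do not appear."""
    return sorted(
        (str(r.study), str(r.factor), int(r.n_levels)) for r in _run(rdf, "count_levels")
    )


def q_group_sizes(rdf: TripleSink) -> list[tuple[str, str, int]]:
    """Rows (study, combination, size) with the combination rendered as
    sorted ``factor=level`` pairs joined by ``;``."""
    per_group: dict[tuple[str, str], tuple[list, int]] = {}
    for r in _run(rdf, "group_sizes"):
        key = (str(r.study), str(r.group))
        pairs, _ = per_group.setdefault(key, ([], int(r.size)))
        pairs.append(f"{r.factor}={r.level}")
    return sorted(
        (study, ";".join(sorted(pairs)), size)
        for (study, _), (pairs, size) in per_group.items()
    )


def q_min_max(rdf: TripleSink) -> list[tuple[str, int, int]]:
    """Rows (study, min group size, max group size); studies without
    groups are omitted."""
    return sorted(
        (str(r.study), int(r.min_size), int(r.max_size)) for r in _run(rdf, "min_max")
    )


def check_balanced(rdf: TripleSink) -> list[tuple[str, bool]]:
    """Rows (study, balanced?) — balanced means min size equals max."""
    return sorted((str(r.study), bool(r.balanced)) for r in _run(rdf, "balanced"))


def _balanced_class(balanced_class_iri, mappings: MappingSet | None) -> URIRef:
    if balanced_class_iri:
        return URIRef(str(balanced_class_iri))
    if mappings is not None:
        row = mappings.lookup_type(BALANCED_DESIGN)
        if row is not None:
            return URIRef(row.class_iri)
    raise ConfigurationError(
        "no balanced-design class: pass balanced_class_iri or load a mapping "
        "set with a 'balanced design' entry"
    )


def annotate_balanced(
    rdf: TripleSink,
    balanced_class_iri: str | None = None,
    mappings: MappingSet | None = None,
) -> TripleSink:
    """Add the balanced-design type triple for each balanced study.

    Idempotent: re-running adds nothing.  A design already carrying the
    balanced class in a study whose recomputed sizes are imbalanced is
    reported as a discrepancy in ``rdf.messages`` and left in place.
    """
    cls = _balanced_class(balanced_class_iri, mappings)
    constructed = rdf.graph.query(
        _prepared("annotate_balanced"), initBindings={"balancedClass": cls}
    )
    for triple in constructed:
        rdf.graph.add(triple)
    # discrepancy scan: pre-annotated balanced designs now imbalanced
    from rdflib.namespace import RDF

    from .vocab import ISA_TERMS
    has_design = URIRef(ISA_TERMS + "hasDesign")
    identifier = URIRef(ISA_TERMS + "identifier")
    balanced_now = dict(check_balanced(rdf))
    for s, d in rdf.graph.subject_objects(has_design):
        if (d, RDF.type, cls) not in rdf.graph:
            continue
        for sid in rdf.graph.objects(s, identifier):
            if balanced_now.get(str(sid)) is False:
                msg = (
                    f"study {sid}: design annotated balanced but computed "
                    "group sizes are imbalanced"
                )
                if msg not in rdf.messages:
                    rdf.messages.append(msg)
    return rdf


@dataclass
class DesignReport:
    """Per-study digest of the design interrogation suite."""

    study: str
    factors: dict[str, list[str]] = field(default_factory=dict)
    level_counts: dict[str, int] = field(default_factory=dict)
    groups: list[tuple[str, int]] = field(default_factory=list)
    min_size: int | None = None
    max_size: int | None = None
    balanced: bool | None = None
    annotation_added: bool = False
    discrepancies: list[str] = field(default_factory=list)


def design_report(
    rdf: TripleSink,
    annotate: bool = False,
    balanced_class_iri: str | None = None,
    mappings: MappingSet | None = None,
) -> list[DesignReport]:
    """Run the whole suite and assemble one report per study."""
    reports: dict[str, DesignReport] = {}

    def rep(study: str) -> DesignReport:
        return reports.setdefault(study, DesignReport(study))

    for study, factor, level in q_factors_levels(rdf):
        rep(study).factors.setdefault(factor, []).append(level)
    for study, factor, n in q_count_levels(rdf):
        rep(study).level_counts[factor] = n
    for study, combination, size in q_group_sizes(rdf):
        rep(study).groups.append((combination, size))
    for study, lo, hi in q_min_max(rdf):
        rep(study).min_size, rep(study).max_size = lo, hi
    for study, flag in check_balanced(rdf):
        rep(study).balanced = flag
    if annotate:
        before = len(rdf)
        annotate_balanced(rdf, balanced_class_iri, mappings)
        added = len(rdf) - before
        for report in reports.values():
            if report.balanced:
                report.annotation_added = added > 0
        for msg in rdf.messages:
            for report in reports.values():
                if f"study {report.study}:" in msg and msg not in report.discrepancies:
                    report.discrepancies.append(msg)
    return [reports[k] for k in sorted(reports)]
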