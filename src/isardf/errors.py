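"""Exception hierarchy for ISA-Tab parsing, mapping and conversion."""


class IsaRdfError(Exception):
    """Base class for all package errors."""


class IsaTabFormatError(IsaRdfError):
    """Malformed ISA-Tab content (missing sections, missing table files)."""


class MappingFormatError(IsaRdfError):
    """Malformed mapping file (bad arity, relative IRI in an IRI field)."""


class GraphStructureError(IsaRdfError):
    """The recovered experiment graph violates a structural constraint
    (e.g. a cycle)."""


class ValidationError(IsaRdfError):
    """Semantically inconsistent metadata, e.g. conflicting factor levels
    for one sample."""


class ConfigurationError(IsaRdfError):
    """Invalid runtime configuration (non-absolute base IRI, missing
    balanced-design class)."""


class FixtureSpecError(IsaRdfError):
    """Inconsistent synthetic-archive specification."""
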