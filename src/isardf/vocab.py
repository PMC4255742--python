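"""Default ISA vocabulary namespace and the element names used internally.

The conversion engine never hardcodes ontology IRIs: every class and
property is resolved through the loaded mapping set.  When no mapping row
matches, a fallback IRI is minted in a configurable ISA vocabulary
namespace, so the output is always well-formed RDF even with an empty
mapping set.
"""

from __future__ import annotations

import re

#: Default namespace for ISA vocabulary fallback terms (configurable).
ISA_TERMS = "http://purl.org/isaterms/"

# Syntactic element names, as they appear in mapping files.
INVESTIGATION = "Investigation"
STUDY = "Study"
STUDY_DESIGN = "Study Design"
STUDY_FACTOR = "Study Factor"
STUDY_ASSAY = "Study Assay"
STUDY_PROTOCOL = "Study Protocol"
STUDY_GROUP = "Study Group"
FACTOR_VALUE_ELEMENT = "Factor Value"
SOURCE_NAME = "Source Name"
SAMPLE_NAME = "Sample Name"
EXTRACT_NAME = "Extract Name"
LABELED_EXTRACT_NAME = "Labeled Extract Name"
MATERIAL = "Material"
RAW_DATA_FILE = "Raw Data File"
DERIVED_DATA_FILE = "Derived Data File"
DATA_FILE = "Data File"
PROTOCOL_REF = "Protocol REF"

# Property vocabulary (3-field mapping rows may override any of these).
HAS_PART = "has part"
HAS_DESIGN = "has design"
HAS_FACTOR = "has factor"
HAS_LEVEL = "has level"
HAS_GROUP = "has group"
HAS_MEMBER = "has member"
HAS_SIZE = "has size"
HAS_ASSAY = "has assay"
HAS_PROTOCOL = "has protocol"
HAS_INPUT = "has input"
HAS_OUTPUT = "has output"
EXECUTES_PROTOCOL = "executes protocol"
HAS_CHARACTERISTIC = "has characteristic"
HAS_PARAMETER_VALUE = "has parameter value"
HAS_UNIT = "has unit"
IDENTIFIER = "identifier"

BALANCED_DESIGN = "balanced design"


def fallback_iri(element: str, namespace: str = ISA_TERMS) -> str:
    """Mint a deterministic fallback IRI for an unmapped element name.

    Spaces become underscores; bracket qualifiers and other characters
    unsafe in an IRI path segment are reduced to underscores as well,
    collapsing runs.  ``fallback_iri("Frobnicator")`` ends in
    ``/Frobnicator``.
    """
    token = re.sub(r"[^A-Za-z0-9._:-]+", "_", element.strip()).strip("_")
    token = token.replace(":", "_")
    return namespace + token
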