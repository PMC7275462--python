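"""Status-label mapping tables and cross-standard conversion.

External systems carry richer status vocabularies than the three-label
interoperability layer.  The two published mappings are total on their
domains and deterministic; collapsing a richer vocabulary onto three
labels is deliberately lossy, so readers keep the original token in
record provenance.  An out-of-domain token raises
:class:`~mii_consent.errors.UnmappedLabelError` rather than defaulting to
``unknown`` — ``unknown`` is reserved for absence of documentation, not
vocabulary drift.

The FHIR table applies identically to Release 3 (v3.0.1) and Release 4
(v4.0.0); the gICS table reflects gICS version 2.8.6.
"""

from __future__ import annotations

from .errors import UnmappedLabelError
from .fhir import FhirDialect, read_fhir_consent, write_fhir_consent
from .bppc import read_bppc, write_bppc
from .model import StatusLabel
from .registry import CodeRegistry

__all__ = [
    "FHIR_STATUS_MAP",
    "GICS_STATUS_MAP",
    "map_fhir_status",
    "map_gics_status",
    "convert",
    "read_any",
    "write_any",
    "DIALECTS",
]

#: FHIR Consent resource status -> interoperability label. Only "active"
#: means the documented permissions are in effect.
FHIR_STATUS_MAP: dict[str, StatusLabel] = {
    "draft": StatusLabel.NOT_VALID,
    "proposed": StatusLabel.NOT_VALID,
    "active": StatusLabel.VALID,
    "rejected": StatusLabel.NOT_VALID,
    "inactive": StatusLabel.NOT_VALID,
    "entered-in-error": StatusLabel.NOT_VALID,
}

#: gICS consent-management status -> interoperability label. Only
#: "Accepted" means the documented permissions are in effect.
GICS_STATUS_MAP: dict[str, StatusLabel] = {
    "Accepted": StatusLabel.VALID,
    "Declined": StatusLabel.NOT_VALID,
    "Withdrawn": StatusLabel.NOT_VALID,
    "Invalidated": StatusLabel.NOT_VALID,
}


def map_fhir_status(label: str) -> StatusLabel:
    """Map a FHIR Consent ``status`` token onto the three-label space."""
    try:
        return FHIR_STATUS_MAP[label]
    except KeyError:
        raise UnmappedLabelError(
            f"FHIR status {label!r} is outside the published mapping domain "
            f"{sorted(FHIR_STATUS_MAP)}"
        ) from None


def map_gics_status(label: str) -> StatusLabel:
    """Map a gICS consent state token onto the three-label space."""
    try:
        return GICS_STATUS_MAP[label]
    except KeyError:
        raise UnmappedLabelError(
            f"gICS status {label!r} is outside the published mapping domain "
            f"{sorted(GICS_STATUS_MAP)}"
        ) from None


DIALECTS = ("fhir-r3", "fhir-r4", "bppc")


def read_any(text: str, dialect: str, registry: CodeRegistry):
    """Parse a document in the named dialect into consent records."""
    if dialect == "fhir-r4":
        return read_fhir_consent(text, FhirDialect.R4, registry)
    if dialect == "fhir-r3":
        return read_fhir_consent(text, FhirDialect.R3, registry)
    if dialect == "bppc":
        return read_bppc(text, registry)
    raise ValueError(f"unknown dialect {dialect!r} (expected one of {DIALECTS})")


def write_any(records, dialect: str) -> str:
    """Serialise consent records in the named dialect."""
    if dialect == "fhir-r4":
        return write_fhir_consent(records, FhirDialect.R4)
    if dialect == "fhir-r3":
        return write_fhir_consent(records, FhirDialect.R3)
    if dialect == "bppc":
        return write_bppc(records)
    raise ValueError(f"unknown dialect {dialect!r} (expected one of {DIALECTS})")


def convert(
    text: str, from_dialect: str, to_dialect: str, registry: CodeRegistry
) -> str:
    """Convert one consent document between dialects through the shared
    record model.  The three core data elements — policy code (carrying
    the template version), status, and validity period — are preserved
    exactly."""
    records = read_any(text, from_dialect, registry)
    return write_any(records, to_dialect)
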