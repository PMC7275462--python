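"""HL7 FHIR Consent resource reader/writer (JSON), Releases 3 and 4.

The mapping to the shared record model:

* the policy-status code travels in the ``policy`` attribute, one URI per
  record (RetrieveCode spelling on write; bare OID, ``urn:oid:`` and
  RetrieveCode spellings accepted on read);
* the validity period is ``provision.period`` in R4 and the resource-root
  ``period`` in R3 (R3 has no ``provision``);
* the patient travels in ``patient.identifier``;
* the ``category`` coding is always LOINC 57016-8 ("consent document");
* R4 resources additionally carry the ``scope`` coding
  ``consentscope/patient-privacy``; R3 resources do not.

FHIR's own ``status`` field is written as ``active``: in this layer the
consent status lives in the policy-status code, not in the resource
lifecycle status.  On read a non-active status is mapped through the
published status table and kept as provenance (``notes``); it never
overrides the policy code's label.
"""

from __future__ import annotations

import enum
import json
from datetime import date
from typing import Sequence

from .errors import FormatError, ValidationError
from .model import (
    ConsentRecord,
    PatientRef,
    SourceDialect,
    ValidityPeriod,
)
from .registry import CodeRegistry, retrieve_code_uri

__all__ = ["FhirDialect", "read_fhir_consent", "write_fhir_consent"]

LOINC_SYSTEM = "http://loinc.org"
LOINC_CONSENT_DOCUMENT = "57016-8"
CONSENT_SCOPE_SYSTEM = "http://terminology.hl7.org/CodeSystem/consentscope"
CONSENT_SCOPE_CODE = "patient-privacy"


class FhirDialect(enum.Enum):
    """Supported FHIR releases. R4 documents carry a ``scope`` element;
    R3 documents do not and place the period at the resource root."""

    R3 = "3.0.1"
    R4 = "4.0.0"

    @property
    def source_dialect(self) -> SourceDialect:
        return SourceDialect.FHIR_R4 if self is FhirDialect.R4 else SourceDialect.FHIR_R3


def _normalise_identifier_system(system: str | None) -> str | None:
    if system and system.startswith("urn:oid:"):
        return system[len("urn:oid:"):]
    return system


def _identifier_system_uri(system: str | None) -> str | None:
    if system is None:
        return None
    # bare OIDs are rendered in their URN form, as FHIR identifier systems
    # must be URIs
    if all(seg.isdigit() for seg in system.split(".")) and "." in system:
        return f"urn:oid:{system}"
    return system


def read_fhir_consent(
    text: str, dialect: FhirDialect, registry: CodeRegistry
) -> list[ConsentRecord]:
    """Parse a FHIR Consent resource into one record per policy entry.

    All policy entries of one resource share the patient and the validity
    period (a Consent resource carries a single period).
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not well-formed JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("resourceType") != "Consent":
        raise FormatError(
            f"expected resourceType 'Consent', got "
            f"{doc.get('resourceType') if isinstance(doc, dict) else type(doc).__name__!r}"
        )

    identifier = (doc.get("patient") or {}).get("identifier") or {}
    value = identifier.get("value")
    if not value:
        raise ValidationError("Consent resource lacks patient.identifier.value")
    patient = PatientRef(
        identifier_value=value,
        identifier_system=_normalise_identifier_system(identifier.get("system")),
    )

    if dialect is FhirDialect.R4:
        period_raw = (doc.get("provision") or {}).get("period") or {}
    else:
        period_raw = doc.get("period") or {}
    start = period_raw.get("start")
    if not start:
        raise ValidationError("Consent resource lacks a validity period start")
    period = ValidityPeriod(
        start=date.fromisoformat(start),
        end=date.fromisoformat(period_raw["end"]) if period_raw.get("end") else None,
    )

    policies = doc.get("policy") or []
    if not policies:
        raise ValidationError("Consent resource lists no policy entries")

    notes: dict[str, str] = {}
    fhir_status = doc.get("status")
    if fhir_status is not None:
        notes["fhir_status"] = fhir_status

    records = []
    for entry in policies:
        uri = entry.get("uri") if isinstance(entry, dict) else entry
        if not uri:
            raise ValidationError("policy entry lacks a uri")
        code = registry.lookup(uri)  # NotFoundError if unresolvable
        records.append(
            ConsentRecord(
                patient=patient,
                code=code,
                period=period,
                source_dialect=dialect.source_dialect,
                document_id=doc.get("id"),
                notes=dict(notes),
            )
        )
    return records


def write_fhir_consent(
    records: Sequence[ConsentRecord],
    dialect: FhirDialect,
    document_id: str | None = None,
) -> str:
    """Serialise records sharing one patient and one period as a FHIR
    Consent resource (JSON text)."""
    if not records:
        raise ValidationError("cannot serialise an empty record list")
    patients = {r.patient for r in records}
    if len(patients) > 1:
        raise ValidationError(
            "all records of one Consent resource must share one patient"
        )
    periods = {r.period for r in records}
    if len(periods) > 1:
        raise ValidationError(
            "a Consent resource carries a single period; split records "
            "with differing periods into separate documents"
        )
    record = records[0]

    doc: dict = {"resourceType": "Consent"}
    if document_id or record.document_id:
        doc["id"] = document_id or record.document_id
    doc["status"] = "active"
    if dialect is FhirDialect.R4:
        doc["scope"] = {
            "coding": [
                {"system": CONSENT_SCOPE_SYSTEM, "code": CONSENT_SCOPE_CODE}
            ]
        }
    doc["category"] = [
        {"coding": [{"system": LOINC_SYSTEM, "code": LOINC_CONSENT_DOCUMENT}]}
    ]
    identifier: dict = {"value": record.patient.identifier_value}
    system_uri = _identifier_system_uri(record.patient.identifier_system)
    if system_uri:
        identifier["system"] = system_uri
    doc["patient"] = {"identifier": identifier}
    doc["policy"] = [{"uri": retrieve_code_uri(r.code)} for r in records]
    period: dict = {"start": record.period.start.isoformat()}
    if record.period.end is not None:
        period["end"] = record.period.end.isoformat()
    if dialect is FhirDialect.R4:
        doc["provision"] = {"period": period}
    else:
        doc["period"] = period
    return json.dumps(doc, indent=2)
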