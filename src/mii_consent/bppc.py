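"""IHE BPPC reader/writer: CDA R2 documents, header-level encoding.

BPPC documents acknowledge privacy-consent policies but have no status
attribute — which is exactly why this layer uses combined policy-status
codes.  Each acknowledged code is carried in one
``documentationOf/serviceEvent`` element:

* ``code`` / ``codeSystem`` attributes hold the policy-status code OID and
  its code system OID;
* ``effectiveTime/low`` and ``effectiveTime/high`` hold the validity
  period in ``YYYYMMDD`` (day precision; finer precision on read is
  truncated with a warning);
* the patient is ``recordTarget/patientRole/id`` (``extension`` =
  identifier value, ``root`` = identifier system).

Only the CDA header is modelled; the structured body is an opaque
placeholder echoed verbatim on round-trip.
"""

from __future__ import annotations

import logging
from datetime import date, datetime
from typing import Sequence

from lxml import etree

from .errors import FormatError, ValidationError
from .model import (
    ConsentRecord,
    Oid,
    PatientRef,
    SourceDialect,
    ValidityPeriod,
)
from .registry import CodeRegistry

__all__ = [
    "read_bppc",
    "write_bppc",
    "validate_bppc_header",
    "BPPC_TEMPLATE_IDS",
    "SERVICE_EVENT_TEMPLATE_ID",
]

log = logging.getLogger(__name__)

CDA_NS = "urn:hl7-org:v3"
NSMAP = {None: CDA_NS}
_NS = {"cda": CDA_NS}

#: Document-level templateIds required by the BPPC profile.
BPPC_TEMPLATE_IDS = (
    Oid("1.3.6.1.4.1.19376.1.5.3.1.1.1"),
    Oid("1.3.6.1.4.1.19376.1.5.3.1.1.7"),
)
#: templateId carried by every consent serviceEvent.
SERVICE_EVENT_TEMPLATE_ID = Oid("1.3.6.1.4.1.19376.1.5.3.1.2.6")

LOINC_OID = "2.16.840.1.113883.6.1"
DOCUMENT_CODE = "57016-8"
DOCUMENT_DISPLAY = "PATIENT PRIVACY ACKNOWLEDGEMENT"

#: Arc under which generated serviceEvent ids are allocated. 2.999 is the
#: example/documentation OID arc, so generated ids can never collide with
#: production identifiers.
DEFAULT_EVENT_ID_ARC = Oid("2.999.2")


def _q(tag: str) -> str:
    return f"{{{CDA_NS}}}{tag}"


def _parse_hl7_date(value: str) -> date:
    digits = value.strip()
    if len(digits) > 8:
        log.warning(
            "effectiveTime value %r carries sub-day precision; truncating to day",
            value,
        )
        digits = digits[:8]
    if len(digits) != 8 or not digits.isdigit():
        raise FormatError(f"unparseable effectiveTime value {value!r} (want YYYYMMDD)")
    try:
        return datetime.strptime(digits, "%Y%m%d").date()
    except ValueError as exc:
        raise FormatError(f"unparseable effectiveTime value {value!r}: {exc}") from exc


def _hl7_date(d: date) -> str:
    return d.strftime("%Y%m%d")


def read_bppc(text: str | bytes, registry: CodeRegistry) -> list[ConsentRecord]:
    """Parse a BPPC CDA document: one record per serviceEvent."""
    if isinstance(text, str):
        text = text.encode("utf-8")
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"not well-formed XML: {exc}") from exc
    if root.tag != _q("ClinicalDocument"):
        raise FormatError(
            f"expected ClinicalDocument in namespace {CDA_NS}, got {root.tag!r}"
        )

    id_el = root.find("cda:recordTarget/cda:patientRole/cda:id", _NS)
    if id_el is None or not id_el.get("extension"):
        raise ValidationError("document lacks recordTarget/patientRole/id")
    patient = PatientRef(
        identifier_value=id_el.get("extension"),
        identifier_system=id_el.get("root"),
    )

    document_id = None
    doc_id_el = root.find("cda:id", _NS)
    if doc_id_el is not None:
        document_id = doc_id_el.get("extension") or doc_id_el.get("root")

    records = []
    for service_event in root.findall(
        "cda:documentationOf/cda:serviceEvent", _NS
    ):
        code_el = service_event.find("cda:code", _NS)
        if code_el is None or not code_el.get("code"):
            raise ValidationError("serviceEvent lacks a code element")
        code = registry.lookup(code_el.get("code"))
        declared_system = code_el.get("codeSystem")
        if declared_system and Oid(declared_system) != code.code_system_oid:
            raise ValidationError(
                f"serviceEvent declares codeSystem {declared_system} but code "
                f"{code.code_oid} is registered under {code.code_system_oid}"
            )
        low_el = service_event.find("cda:effectiveTime/cda:low", _NS)
        if low_el is None or not low_el.get("value"):
            raise ValidationError("serviceEvent lacks effectiveTime/low")
        high_el = service_event.find("cda:effectiveTime/cda:high", _NS)
        period = ValidityPeriod(
            start=_parse_hl7_date(low_el.get("value")),
            end=_parse_hl7_date(high_el.get("value"))
            if high_el is not None and high_el.get("value")
            else None,
        )
        records.append(
            ConsentRecord(
                patient=patient,
                code=code,
                period=period,
                source_dialect=SourceDialect.BPPC,
                document_id=document_id,
            )
        )
    return records


def write_bppc(
    records: Sequence[ConsentRecord],
    document_id: str | None = None,
    event_id_arc: Oid | str = DEFAULT_EVENT_ID_ARC,
) -> str:
    """Serialise records sharing one patient as a BPPC CDA document, one
    serviceEvent per record, order preserved."""
    if not records:
        raise ValidationError("cannot serialise an empty record list")
    patients = {r.patient for r in records}
    if len(patients) > 1:
        raise ValidationError(
            "all records of one BPPC document must share one patient"
        )
    record = records[0]
    arc = Oid(event_id_arc)

    root = etree.Element(_q("ClinicalDocument"), nsmap=NSMAP)
    for template_oid in BPPC_TEMPLATE_IDS:
        etree.SubElement(root, _q("templateId"), root=str(template_oid))
    doc_id = document_id or record.document_id
    if doc_id:
        etree.SubElement(root, _q("id"), extension=doc_id, root=str(arc))
    etree.SubElement(
        root,
        _q("code"),
        code=DOCUMENT_CODE,
        displayName=DOCUMENT_DISPLAY,
        codeSystem=LOINC_OID,
        codeSystemName="LOINC",
    )

    record_target = etree.SubElement(root, _q("recordTarget"))
    patient_role = etree.SubElement(record_target, _q("patientRole"))
    id_attrs = {"extension": record.patient.identifier_value}
    if record.patient.identifier_system:
        id_attrs["root"] = record.patient.identifier_system
    etree.SubElement(patient_role, _q("id"), **id_attrs)
    # minimal demographic placeholders; real content is out of scope here
    etree.SubElement(patient_role, _q("addr"), use="HP")
    etree.SubElement(patient_role, _q("patient"))

    for i, r in enumerate(records, start=1):
        documentation_of = etree.SubElement(
            root, _q("documentationOf"), typeCode="DOC"
        )
        service_event = etree.SubElement(
            documentation_of, _q("serviceEvent"), classCode="ACT", moodCode="EVN"
        )
        etree.SubElement(
            service_event, _q("templateId"), root=str(SERVICE_EVENT_TEMPLATE_ID)
        )
        etree.SubElement(service_event, _q("id"), root=str(arc.child(i)))
        etree.SubElement(
            service_event,
            _q("code"),
            code=str(r.code.code_oid),
            codeSystem=str(r.code.code_system_oid),
        )
        effective_time = etree.SubElement(service_event, _q("effectiveTime"))
        etree.SubElement(
            effective_time, _q("low"), value=_hl7_date(r.period.start)
        )
        if r.period.end is not None:
            etree.SubElement(
                effective_time, _q("high"), value=_hl7_date(r.period.end)
            )

    component = etree.SubElement(root, _q("component"))
    etree.SubElement(component, _q("structuredBody"))  # opaque placeholder

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def validate_bppc_header(text: str | bytes) -> list[str]:
    """Structural check of a BPPC document header against this package's
    relaxed profile: namespace, required templateIds, document code, a
    patient id, and well-formed serviceEvents.  Returns a list of problem
    descriptions; empty = conformant."""
    problems: list[str] = []
    if isinstance(text, str):
        text = text.encode("utf-8")
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        return [f"not well-formed XML: {exc}"]
    if root.tag != _q("ClinicalDocument"):
        return [f"root element is {root.tag!r}, not ClinicalDocument in {CDA_NS}"]
    declared = {
        el.get("root") for el in root.findall("cda:templateId", _NS)
    }
    for template_oid in BPPC_TEMPLATE_IDS:
        if str(template_oid) not in declared:
            problems.append(f"missing document templateId {template_oid}")
    code_el = root.find("cda:code", _NS)
    if code_el is None or code_el.get("code") != DOCUMENT_CODE:
        problems.append(f"document code is not LOINC {DOCUMENT_CODE}")
    elif code_el.get("codeSystem") != LOINC_OID:
        problems.append(f"document code system is not {LOINC_OID}")
    if root.find("cda:recordTarget/cda:patientRole/cda:id", _NS) is None:
        problems.append("missing recordTarget/patientRole/id")
    events = root.findall("cda:documentationOf/cda:serviceEvent", _NS)
    if not events:
        problems.append("no documentationOf/serviceEvent elements")
    for i, event in enumerate(events, start=1):
        templates = {
            el.get("root") for el in event.findall("cda:templateId", _NS)
        }
        if str(SERVICE_EVENT_TEMPLATE_ID) not in templates:
            problems.append(
                f"serviceEvent {i} lacks templateId {SERVICE_EVENT_TEMPLATE_ID}"
            )
        if event.get("classCode") != "ACT" or event.get("moodCode") != "EVN":
            problems.append(f"serviceEvent {i} lacks classCode ACT / moodCode EVN")
        if event.find("cda:code", _NS) is None:
            problems.append(f"serviceEvent {i} lacks a code element")
        if event.find("cda:effectiveTime/cda:low", _NS) is None:
            problems.append(f"serviceEvent {i} lacks effectiveTime/low")
    return problems
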