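"""Core data model of the consent interoperability layer.

The layer represents one documented statement about a data-use policy as a
:class:`ConsentRecord`: *which patient*, *which policy in which template
version with which status* (a :class:`PolicyStatusCode`), and *from when,
optionally until when* (a :class:`ValidityPeriod`).  Three mandatory data
elements must always be present: the consent status for each module, the
template version (carried inside the policy reference), and the start date
of validity.

Status is three-valued (:class:`StatusLabel`): ``valid`` / ``not valid`` /
``unknown``.  ``unknown`` denotes absence of documentation, never a mapped
foreign vocabulary token.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ValidationError

__all__ = [
    "StatusLabel",
    "Oid",
    "oid_to_urn",
    "urn_to_oid",
    "Module",
    "ConsentTemplate",
    "load_template",
    "PolicyKind",
    "Policy",
    "PolicyStatusCode",
    "ValidityPeriod",
    "PatientRef",
    "SourceDialect",
    "ConsentRecord",
]


class StatusLabel(enum.Enum):
    """Three-valued interoperability status of a policy.

    Exactly three members exist; the string rendering is the
    interoperable token ("valid", "not valid", "unknown").
    """

    VALID = "valid"
    NOT_VALID = "not valid"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # exact interoperable token
        return self.value

    @classmethod
    def parse(cls, token: str) -> "StatusLabel":
        try:
            return cls(token)
        except ValueError:
            raise ValidationError(
                f"not a status label: {token!r} (expected one of "
                f"'valid', 'not valid', 'unknown')"
            ) from None


_OID_SEGMENT = re.compile(r"^(0|[1-9][0-9]*)$")


class Oid(str):
    """Object Identifier: a dotted path of non-negative integers naming a
    node in a hierarchical namespace (e.g. ``2.16.840.1.113883.3.1937.777.24.5.1``).

    Behaves as a plain string; construction validates.  A child OID equals
    its parent plus ``"." + integer``.
    """

    __slots__ = ()

    def __new__(cls, value: str) -> "Oid":
        if isinstance(value, Oid):
            return super().__new__(cls, value)
        if not isinstance(value, str) or not value:
            raise ValidationError(f"OID must be a non-empty string, got {value!r}")
        for i, segment in enumerate(value.split(".")):
            if not _OID_SEGMENT.match(segment):
                raise ValidationError(
                    f"malformed OID {value!r}: segment {i + 1} ({segment!r}) "
                    f"is not a non-negative integer"
                )
        return super().__new__(cls, value)

    @property
    def segments(self) -> tuple[int, ...]:
        return tuple(int(s) for s in self.split("."))

    def child(self, index: int) -> "Oid":
        if index < 0:
            raise ValidationError(f"child index must be non-negative, got {index}")
        return Oid(f"{self}.{index}")

    def is_child_of(self, parent: "Oid | str") -> bool:
        """True iff this OID is a *direct* child of ``parent``."""
        prefix = str(parent) + "."
        return self.startswith(prefix) and "." not in self[len(prefix):]

    @property
    def parent(self) -> "Oid | None":
        head, sep, _ = self.rpartition(".")
        return Oid(head) if sep else None

    @property
    def urn(self) -> str:
        return oid_to_urn(self)


def oid_to_urn(oid: Oid | str) -> str:
    """Render an OID as its URN form, ``urn:oid:<dotted path>``."""
    return f"urn:oid:{Oid(oid)}"


def urn_to_oid(urn: str) -> Oid:
    """Parse a ``urn:oid:`` URN back to a validated :class:`Oid`.

    Exact inverse of :func:`oid_to_urn`.
    """
    prefix = "urn:oid:"
    if not urn.startswith(prefix):
        raise ValidationError(f"not an OID URN (expected '{prefix}...'): {urn!r}")
    return Oid(urn[len(prefix):])


@dataclass(frozen=True)
class Module:
    """A logically self-contained consent statement carrying its own
    voluntary opt-in decision."""

    module_id: str
    statement_text: str
    section_name: str
    opt_in_choices: tuple[str, ...] = ("Yes", "No")

    def __post_init__(self) -> None:
        if not self.module_id:
            raise ValidationError("module_id must be non-empty")
        object.__setattr__(self, "opt_in_choices", tuple(self.opt_in_choices))
        if not {"Yes", "No"} <= set(self.opt_in_choices):
            raise ValidationError(
                f"module {self.module_id!r} must offer at least the opt-in "
                f"choices 'Yes' and 'No', got {list(self.opt_in_choices)}"
            )


@dataclass(frozen=True)
class ConsentTemplate:
    """A versioned consent document: ordered sections, each holding modules."""

    template_version: str
    sections: tuple[str, ...]
    modules: tuple[Module, ...]

    def __post_init__(self) -> None:
        if not self.template_version:
            raise ValidationError("template_version must be non-empty")
        object.__setattr__(self, "sections", tuple(self.sections))
        object.__setattr__(self, "modules", tuple(self.modules))
        if not self.sections:
            raise ValidationError("template must declare at least one section")
        section_set = set(self.sections)
        if len(section_set) != len(self.sections):
            raise ValidationError("duplicate section names")
        seen: set[str] = set()
        for m in self.modules:
            if m.section_name not in section_set:
                raise ValidationError(
                    f"module {m.module_id!r} references unknown section "
                    f"{m.section_name!r}"
                )
            if m.module_id in seen:
                raise ValidationError(
                    f"duplicate module_id {m.module_id!r} in template "
                    f"version {self.template_version!r}"
                )
            seen.add(m.module_id)

    def module(self, module_id: str) -> Module:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)

    @property
    def module_ids(self) -> tuple[str, ...]:
        return tuple(m.module_id for m in self.modules)


def load_template(source: str | Path) -> ConsentTemplate:
    """Load a consent-template definition file (YAML).

    Schema::

        version: "1.6a"
        sections: [<section name>, ...]
        modules:
          - id: <token>
            section: <section name>
            statement: <free text>
            choices: ["Yes", "No", ...]   # optional, defaults to Yes/No

    Sections and modules are kept in file order.
    """
    path = Path(source)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ValidationError(f"template file {path} does not parse: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"template file {path} must be a mapping")
    version = raw.get("version")
    if not version:
        raise ValidationError(f"template file {path} lacks a version string")
    sections = raw.get("sections") or []
    modules_raw = raw.get("modules") or []
    modules = []
    for entry in modules_raw:
        module_id = entry.get("id", "")
        choices = entry.get("choices", ["Yes", "No"])
        if not isinstance(choices, list) or not choices:
            raise ValidationError(
                f"module {module_id!r}: opt-in choices missing or empty"
            )
        # YAML readers may turn unquoted Yes/No into booleans; normalise.
        choices = ["Yes" if c is True else "No" if c is False else str(c) for c in choices]
        modules.append(
            Module(
                module_id=str(module_id),
                statement_text=str(entry.get("statement", "")),
                section_name=str(entry.get("section", "")),
                opt_in_choices=tuple(choices),
            )
        )
    return ConsentTemplate(
        template_version=str(version),
        sections=tuple(str(s) for s in sections),
        modules=tuple(modules),
    )


class PolicyKind(enum.Enum):
    CONSENT_MODULE = "consent_module"
    REGULATORY = "regulatory"


@dataclass(frozen=True)
class Policy:
    """A consent module of a specific template version, or a regulatory
    data-use provision (which carries no template version)."""

    policy_id: str
    kind: PolicyKind
    template_version: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.policy_id:
            raise ValidationError("policy_id must be non-empty")
        if self.kind is PolicyKind.CONSENT_MODULE and not self.template_version:
            raise ValidationError(
                f"consent-module policy {self.policy_id!r} must carry a "
                f"template version"
            )
        if self.kind is PolicyKind.REGULATORY and self.template_version is not None:
            raise ValidationError(
                f"regulatory policy {self.policy_id!r} may not carry a "
                f"template version"
            )

    @property
    def key(self) -> tuple[str, str | None]:
        return (self.policy_id, self.template_version)


@dataclass(frozen=True)
class PolicyStatusCode:
    """A uniquely identified combination of one policy with one status label.

    This combined code is the interoperability primitive: profiles that
    cannot carry an explicit status attribute (IHE BPPC) still transport
    the status, because it is baked into the code itself.
    """

    code_oid: Oid
    code_system_oid: Oid
    policy: Policy
    status: StatusLabel
    display: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "code_oid", Oid(self.code_oid))
        object.__setattr__(self, "code_system_oid", Oid(self.code_system_oid))
        if not self.code_oid.is_child_of(self.code_system_oid):
            raise ValidationError(
                f"code OID {self.code_oid} is not a child of its code system "
                f"{self.code_system_oid}"
            )


def _parse_date(value: "date | str") -> date:
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(value)
    except (TypeError, ValueError):
        raise ValidationError(f"not a calendar date: {value!r}") from None


@dataclass(frozen=True)
class ValidityPeriod:
    """Closed calendar-date interval: ``start`` required, ``end`` optional
    (absent = open-ended).  Both endpoints are inclusive."""

    start: date
    end: date | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", _parse_date(self.start))
        if self.end is not None:
            object.__setattr__(self, "end", _parse_date(self.end))
            if self.start > self.end:
                raise ValidationError(
                    f"validity period start {self.start} is after end {self.end}"
                )

    def contains(self, d: date) -> bool:
        return self.start <= d and (self.end is None or d <= self.end)


@dataclass(frozen=True)
class PatientRef:
    """Reference to the patient a documented status applies to."""

    identifier_value: str
    identifier_system: str | None = None

    def __post_init__(self) -> None:
        if not self.identifier_value:
            raise ValidationError("patient identifier_value must be non-empty")


class SourceDialect(enum.Enum):
    FHIR_R3 = "fhir-r3"
    FHIR_R4 = "fhir-r4"
    BPPC = "bppc"
    NATIVE = "native"


@dataclass(frozen=True)
class ConsentRecord:
    """One documented consent statement.

    The three mandatory data elements — patient, policy-status code
    (carrying the template version), and validity start date — are
    enforced at construction.  Provenance fields (``recorded_at``,
    ``source_dialect``, ``document_id``, ``notes``) do not participate in
    equality: two records are the same documented statement iff patient,
    code and period agree.
    """

    patient: PatientRef
    code: PolicyStatusCode
    period: ValidityPeriod
    recorded_at: datetime | None = field(default=None, compare=False)
    source_dialect: SourceDialect = field(default=SourceDialect.NATIVE, compare=False)
    document_id: str | None = field(default=None, compare=False)
    notes: Mapping[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not isinstance(self.patient, PatientRef):
            raise ValidationError("ConsentRecord requires a patient reference")
        if not isinstance(self.code, PolicyStatusCode):
            raise ValidationError("ConsentRecord requires a policy-status code")
        if not isinstance(self.period, ValidityPeriod) or self.period.start is None:
            raise ValidationError("ConsentRecord requires a validity period start")
        object.__setattr__(self, "notes", dict(self.notes))

    @property
    def core_elements(self) -> tuple:
        """The interoperable payload: what every dialect must preserve."""
        return (
            self.patient.identifier_value,
            self.patient.identifier_system,
            str(self.code.code_oid),
            str(self.code.code_system_oid),
            self.code.policy.template_version,
            self.code.status.value,
            self.period.start,
            self.period.end,
        )
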