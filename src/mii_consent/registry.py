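"""Code registry: code systems, consecutive policy-status code allocation,
and value sets.

This plays the role a public terminology registry (ART-DECOR) plays in
production: it owns the code systems under which every (policy, status)
combination receives a unique consecutive OID, and it serves the value
sets that group the three codes of each policy.

Allocation is gapless and deterministic: modules in template order, and
within a module the status labels in the fixed order valid (1),
not valid (2), unknown (3).  The first module of a template allocated
under system ``S`` therefore receives the codes ``S.1``, ``S.2``, ``S.3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import parse_qs, urlparse

import yaml

from .errors import ConflictError, NotFoundError, ValidationError
from .model import (
    ConsentTemplate,
    Oid,
    Policy,
    PolicyKind,
    PolicyStatusCode,
    StatusLabel,
    urn_to_oid,
)

__all__ = [
    "MII_CONSENT_CODE_SYSTEM_OID",
    "MII_REGULATORY_CODE_SYSTEM_OID",
    "RETRIEVE_CODE_BASE",
    "CodeSystem",
    "ValueSet",
    "CodeRegistry",
    "allocate_codes",
    "retrieve_code_uri",
    "parse_code_reference",
]

#: Code system holding the policy-status codes of the broad-consent template.
MII_CONSENT_CODE_SYSTEM_OID = Oid("2.16.840.1.113883.3.1937.777.24.5.1")
#: Sibling system for regulatory (non-consent) data-use policies.
MII_REGULATORY_CODE_SYSTEM_OID = Oid("2.16.840.1.113883.3.1937.777.24.5.2")

RETRIEVE_CODE_BASE = "http://art-decor.org/decor/services/RetrieveCode"

#: Fixed allocation order of labels within one policy.
_LABEL_ORDER = (StatusLabel.VALID, StatusLabel.NOT_VALID, StatusLabel.UNKNOWN)


@dataclass
class CodeSystem:
    """A set of policy-status codes with well-defined OIDs, allocated as
    consecutive children of ``system_oid``."""

    system_oid: Oid
    name: str = ""
    codes: dict[Oid, PolicyStatusCode] = field(default_factory=dict)
    next_child_index: int = 1

    def _add(self, code: PolicyStatusCode) -> None:
        if code.code_oid in self.codes:
            raise ConflictError(f"code OID {code.code_oid} already registered")
        if not code.code_oid.is_child_of(self.system_oid):
            raise ValidationError(
                f"code {code.code_oid} does not belong under system "
                f"{self.system_oid}"
            )
        self.codes[code.code_oid] = code


@dataclass
class ValueSet:
    """The context-specific selection of codes usable for one policy: its
    three status combinations.  The description carries the template
    version, so consumers can tell template revisions apart."""

    valueset_id: str
    description: str
    member_code_oids: tuple[Oid, ...]


def retrieve_code_uri(code: PolicyStatusCode) -> str:
    """Registry-lookup URI spelling of a code (query parameters ``code``
    and ``codeSystem``), as used inside FHIR ``policy`` entries."""
    return (
        f"{RETRIEVE_CODE_BASE}?code={code.code_oid}"
        f"&codeSystem={code.code_system_oid}"
    )


def parse_code_reference(reference: str) -> Oid:
    """Accept a code reference in any of its three spellings — bare OID,
    ``urn:oid:`` URN, or RetrieveCode-style URI — and return the code OID."""
    ref = reference.strip()
    if ref.startswith("urn:oid:"):
        return urn_to_oid(ref)
    if ref.startswith("http://") or ref.startswith("https://"):
        query = parse_qs(urlparse(ref).query)
        codes = query.get("code", [])
        if len(codes) != 1:
            raise ValidationError(
                f"code URI must carry exactly one 'code' parameter: {ref!r}"
            )
        return Oid(codes[0])
    return Oid(ref)


class CodeRegistry:
    """Owns code systems and value sets; resolves code references."""

    def __init__(self) -> None:
        self.systems: dict[Oid, CodeSystem] = {}
        self.value_sets: dict[str, ValueSet] = {}
        # (policy_id, template_version) -> allocated codes, for conflict
        # detection and reverse lookup
        self._by_policy: dict[tuple[str, str | None], list[PolicyStatusCode]] = {}

    # -- systems -----------------------------------------------------------

    def add_system(self, system_oid: Oid | str, name: str = "") -> CodeSystem:
        oid = Oid(system_oid)
        if oid in self.systems:
            return self.systems[oid]
        system = CodeSystem(system_oid=oid, name=name)
        self.systems[oid] = system
        return system

    # -- allocation --------------------------------------------------------

    def _allocate_policy(
        self, system: CodeSystem, policy: Policy, display_stem: str
    ) -> list[PolicyStatusCode]:
        if policy.key in self._by_policy:
            raise ConflictError(
                f"policy {policy.policy_id!r} (template version "
                f"{policy.template_version!r}) is already registered"
            )
        codes = []
        for label in _LABEL_ORDER:
            code = PolicyStatusCode(
                code_oid=system.system_oid.child(system.next_child_index),
                code_system_oid=system.system_oid,
                policy=policy,
                status=label,
                display=f"{display_stem} — {label}",
            )
            system._add(code)
            system.next_child_index += 1
            codes.append(code)
        self._by_policy[policy.key] = codes
        vs_id = _valueset_id(policy)
        version_note = (
            f"template version {policy.template_version}"
            if policy.template_version is not None
            else "regulatory policy"
        )
        self.value_sets[vs_id] = ValueSet(
            valueset_id=vs_id,
            description=f"Status codes for policy '{policy.policy_id}' ({version_note})",
            member_code_oids=tuple(c.code_oid for c in codes),
        )
        return codes

    def allocate_template(
        self,
        template: ConsentTemplate,
        system_oid: Oid | str = MII_CONSENT_CODE_SYSTEM_OID,
    ) -> list[PolicyStatusCode]:
        """Allocate consecutive policy-status codes for every module of a
        template, three per module, plus one value set per module."""
        system = self.add_system(
            system_oid, name=f"Consent policy-status codes, template "
            f"version {template.template_version}"
        )
        for module in template.modules:
            if (module.module_id, template.template_version) in self._by_policy:
                raise ConflictError(
                    f"module {module.module_id!r} of template version "
                    f"{template.template_version!r} is already registered"
                )
        allocated: list[PolicyStatusCode] = []
        for module in template.modules:
            policy = Policy(
                policy_id=module.module_id,
                kind=PolicyKind.CONSENT_MODULE,
                template_version=template.template_version,
                description=module.statement_text,
            )
            allocated.extend(
                self._allocate_policy(system, policy, module.module_id)
            )
        return allocated

    def allocate_regulatory(
        self,
        policy: Policy,
        system_oid: Oid | str = MII_REGULATORY_CODE_SYSTEM_OID,
    ) -> list[PolicyStatusCode]:
        """Allocate status codes for a regulatory (non-consent) policy under
        the sibling code system reserved for such provisions."""
        if policy.kind is not PolicyKind.REGULATORY:
            raise ValidationError(
                f"policy {policy.policy_id!r} is not a regulatory policy"
            )
        system = self.add_system(system_oid, name="Regulatory data-use policies")
        return self._allocate_policy(system, policy, policy.policy_id)

    # -- lookup ------------------------------------------------------------

    def lookup(self, reference: str) -> PolicyStatusCode:
        """Resolve a code reference (bare OID / urn:oid / RetrieveCode URI)
        to its registered policy-status code."""
        code_oid = parse_code_reference(str(reference))
        system_oid = code_oid.parent
        if system_oid is not None and system_oid in self.systems:
            code = self.systems[system_oid].codes.get(code_oid)
            if code is not None:
                return code
        for system in self.systems.values():  # reference may omit the system
            code = system.codes.get(code_oid)
            if code is not None:
                return code
        raise NotFoundError(
            f"code {code_oid} is not registered", identifier=str(reference)
        )

    def value_set_for(
        self, policy_id: str, template_version: str | None
    ) -> ValueSet:
        """The value set holding exactly the status codes of one policy."""
        codes = self._by_policy.get((policy_id, template_version))
        if codes is None:
            raise NotFoundError(
                f"policy {policy_id!r} (template version {template_version!r}) "
                f"is not registered",
                identifier=policy_id,
            )
        return self.value_sets[_valueset_id(codes[0].policy)]

    def codes_for(
        self, policy_id: str, template_version: str | None
    ) -> list[PolicyStatusCode]:
        codes = self._by_policy.get((policy_id, template_version))
        if codes is None:
            raise NotFoundError(
                f"policy {policy_id!r} (template version {template_version!r}) "
                f"is not registered",
                identifier=policy_id,
            )
        return list(codes)

    def code_for(
        self, policy_id: str, template_version: str | None, status: StatusLabel
    ) -> PolicyStatusCode:
        for code in self.codes_for(policy_id, template_version):
            if code.status is status:
                return code
        raise NotFoundError(  # pragma: no cover - allocation always emits all 3
            f"no {status} code for policy {policy_id!r}", identifier=policy_id
        )

    @property
    def policies(self) -> list[Policy]:
        return [codes[0].policy for codes in self._by_policy.values()]

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "mii-consent-registry/1",
            "code_systems": [
                {
                    "oid": str(system.system_oid),
                    "name": system.name,
                    "next_child_index": system.next_child_index,
                    "codes": [
                        {
                            "oid": str(c.code_oid),
                            "status": c.status.value,
                            "display": c.display,
                            "policy": {
                                "id": c.policy.policy_id,
                                "kind": c.policy.kind.value,
                                "template_version": c.policy.template_version,
                                "description": c.policy.description,
                            },
                        }
                        for c in system.codes.values()
                    ],
                }
                for system in self.systems.values()
            ],
            "value_sets": [
                {
                    "id": vs.valueset_id,
                    "description": vs.description,
                    "members": [str(o) for o in vs.member_code_oids],
                }
                for vs in self.value_sets.values()
            ],
        }

    def export(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, raw: dict) -> "CodeRegistry":
        if not isinstance(raw, dict) or "code_systems" not in raw:
            raise ValidationError("not a registry definition (no code_systems)")
        registry = cls()
        seen_oids: set[Oid] = set()
        policy_codes: dict[tuple[str, str | None], dict[StatusLabel, PolicyStatusCode]] = {}
        for system_raw in raw.get("code_systems", []):
            system = registry.add_system(
                Oid(system_raw["oid"]), system_raw.get("name", "")
            )
            for code_raw in system_raw.get("codes", []):
                oid = Oid(code_raw["oid"])
                if oid in seen_oids:
                    raise ValidationError(f"duplicate code OID on import: {oid}")
                seen_oids.add(oid)
                p = code_raw["policy"]
                policy = Policy(
                    policy_id=p["id"],
                    kind=PolicyKind(p["kind"]),
                    template_version=p.get("template_version"),
                    description=p.get("description", ""),
                )
                code = PolicyStatusCode(
                    code_oid=oid,
                    code_system_oid=system.system_oid,
                    policy=policy,
                    status=StatusLabel.parse(code_raw["status"]),
                    display=code_raw.get("display", ""),
                )
                system._add(code)
                policy_codes.setdefault(policy.key, {})[code.status] = code
            system.next_child_index = int(
                system_raw.get(
                    "next_child_index",
                    max((c.segments[-1] for c in system.codes), default=0) + 1,
                )
            )
        for key, by_label in policy_codes.items():
            registry._by_policy[key] = [
                by_label[label] for label in _LABEL_ORDER if label in by_label
            ]
        for vs_raw in raw.get("value_sets", []):
            members = tuple(Oid(m) for m in vs_raw.get("members", []))
            for member in members:
                registry.lookup(member)  # every member must resolve
            registry.value_sets[vs_raw["id"]] = ValueSet(
                valueset_id=vs_raw["id"],
                description=vs_raw.get("description", ""),
                member_code_oids=members,
            )
        return registry

    @classmethod
    def load(cls, path: str | Path) -> "CodeRegistry":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls.from_dict(raw)


def _valueset_id(policy: Policy) -> str:
    version = policy.template_version or "regulatory"
    return f"vs-{policy.policy_id}-{version}"


def allocate_codes(
    registry: CodeRegistry,
    template: ConsentTemplate,
    system_oid: Oid | str = MII_CONSENT_CODE_SYSTEM_OID,
) -> list[PolicyStatusCode]:
    """Functional wrapper around :meth:`CodeRegistry.allocate_template`."""
    return registry.allocate_template(template, system_oid)
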