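"""Temporal consent-status resolution, cohort queries, and record
validation.

``effective_status`` answers: *is this policy's permission in effect for
this patient on this date?*  Among the records whose validity period
covers the date, the winner is chosen by a deterministic, deny-biased
tie-break:

1. latest ``recorded_at`` (absent counts as earliest possible);
2. latest period start;
3. label order ``not valid`` before ``unknown`` before ``valid``.

No covering record means ``unknown`` — absence of documentation, which is
also how expired or not-yet-started periods resolve.  Withdrawal needs no
special case: it is simply a later ``not valid``-coded record that wins
the tie-break wherever it applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timezone

from .model import (
    ConsentRecord,
    ConsentTemplate,
    PatientRef,
    Policy,
    StatusLabel,
    ValidityPeriod,
)

__all__ = [
    "ConsentStore",
    "EngineConfig",
    "Violation",
    "effective_status",
    "cohort_query",
    "validate_record",
    "DEFAULT_INSURANCE_MODULE_IDS",
]

#: Modules subject to the five-year validity cap on health-insurance data.
DEFAULT_INSURANCE_MODULE_IDS = frozenset({"kvdat_retrieve_5y", "kvdat_retro_5y"})

_EARLIEST = datetime.min.replace(tzinfo=timezone.utc)

#: Deny-biased label preference for exact ties (lower wins).
_LABEL_RANK = {
    StatusLabel.NOT_VALID: 0,
    StatusLabel.UNKNOWN: 1,
    StatusLabel.VALID: 2,
}


def _patient_key(patient: PatientRef) -> tuple[str, str | None]:
    return (patient.identifier_value, patient.identifier_system)


def _policy_key(policy: Policy) -> tuple[str, str | None]:
    return policy.key


@dataclass(frozen=True)
class EngineConfig:
    """Resolution-engine configuration.

    ``insurance_cap_years`` is fixed at 5: permissions on health-insurance
    data may not span more than five years.
    """

    insurance_module_ids: frozenset[str] = DEFAULT_INSURANCE_MODULE_IDS
    insurance_cap_years: int = 5
    expired_reads_as: StatusLabel = StatusLabel.UNKNOWN


class ConsentStore:
    """Collection of consent records indexed by (patient, policy)."""

    def __init__(self, records: list[ConsentRecord] | None = None) -> None:
        self._records: list[ConsentRecord] = []
        self._index: dict[tuple, list[ConsentRecord]] = {}
        self._patients: dict[tuple, PatientRef] = {}
        for record in records or []:
            self.add(record)

    def add(self, record: ConsentRecord) -> None:
        self._records.append(record)
        key = (_patient_key(record.patient), _policy_key(record.code.policy))
        self._index.setdefault(key, []).append(record)
        self._patients.setdefault(_patient_key(record.patient), record.patient)

    def records_for(
        self, patient: PatientRef, policy: Policy
    ) -> list[ConsentRecord]:
        return list(
            self._index.get((_patient_key(patient), _policy_key(policy)), [])
        )

    @property
    def records(self) -> list[ConsentRecord]:
        return list(self._records)

    @property
    def patients(self) -> list[PatientRef]:
        """The patient universe of the store (insertion-order stable)."""
        return list(self._patients.values())

    def __len__(self) -> int:
        return len(self._records)


def _tie_break_key(record: ConsentRecord) -> tuple:
    recorded = record.recorded_at or _EARLIEST
    if recorded.tzinfo is None:
        recorded = recorded.replace(tzinfo=timezone.utc)
    return (recorded, record.period.start, -_LABEL_RANK[record.code.status])


def effective_status(
    store: ConsentStore,
    patient: PatientRef,
    policy: Policy,
    at_date: date,
) -> StatusLabel:
    """Resolve the effective status of ``policy`` for ``patient`` on
    ``at_date``.  Total: always returns one of the three labels."""
    covering = [
        r for r in store.records_for(patient, policy) if r.period.contains(at_date)
    ]
    if not covering:
        return StatusLabel.UNKNOWN
    winner = max(covering, key=_tie_break_key)
    return winner.code.status


def cohort_query(
    store: ConsentStore,
    policy: Policy,
    at_date: date,
    required: StatusLabel,
) -> set[PatientRef]:
    """Exactly the patients whose effective status for ``policy`` on
    ``at_date`` equals ``required``.  For a fixed (policy, date) the three
    cohorts partition the store's patient universe."""
    return {
        patient
        for patient in store.patients
        if effective_status(store, patient, policy, at_date) is required
    }


@dataclass(frozen=True)
class Violation:
    """One validation finding; violations are data, not exceptions."""

    code: str
    message: str


def _add_years(d: date, years: int) -> date:
    try:
        return d.replace(year=d.year + years)
    except ValueError:  # Feb 29 -> Feb 28
        return d.replace(year=d.year + years, day=28)


def max_capped_end(start: date, cap_years: int) -> date:
    """Latest inclusive end date of a period starting ``start`` that spans
    at most ``cap_years`` years (e.g. 2018-10-10 -> 2023-10-09)."""
    from datetime import timedelta

    return _add_years(start, cap_years) - timedelta(days=1)


def validate_record(
    record: ConsentRecord,
    template: ConsentTemplate | None = None,
    config: EngineConfig = EngineConfig(),
) -> list[Violation]:
    """Check a record against the template and the five-year insurance
    cap.  Empty report = valid."""
    violations: list[Violation] = []
    policy = record.code.policy

    if record.period is None or record.period.start is None:
        violations.append(
            Violation("missing-start", "record lacks a validity period start")
        )
        return violations

    if template is not None and policy.template_version is not None:
        if policy.template_version != template.template_version:
            violations.append(
                Violation(
                    "template-mismatch",
                    f"record cites template version {policy.template_version!r} "
                    f"but validating against {template.template_version!r}",
                )
            )
        elif policy.policy_id not in template.module_ids:
            violations.append(
                Violation(
                    "template-mismatch",
                    f"module {policy.policy_id!r} is not part of template "
                    f"version {template.template_version!r}",
                )
            )

    # the cap constrains how long the *permission* may run; records coding
    # "not valid" or "unknown" grant nothing and are exempt
    if (
        policy.policy_id in config.insurance_module_ids
        and record.code.status is StatusLabel.VALID
    ):
        cap_end = max_capped_end(record.period.start, config.insurance_cap_years)
        if record.period.end is None:
            violations.append(
                Violation(
                    "duration",
                    f"insurance-data module {policy.policy_id!r} requires a "
                    f"bounded period of at most {config.insurance_cap_years} "
                    f"years; period is open-ended",
                )
            )
        elif record.period.end > cap_end:
            violations.append(
                Violation(
                    "duration",
                    f"insurance-data module {policy.policy_id!r} period "
                    f"{record.period.start}..{record.period.end} exceeds the "
                    f"{config.insurance_cap_years}-year cap (latest allowed "
                    f"end: {cap_end})",
                )
            )
    return violations
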