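"""Deterministic synthetic consent populations.

The generator emulates the decision structure of a modular opt-in
consent: every patient signs one consent document on an enrollment date,
answering Yes or No to each module; a fraction of the opted-in patients
later withdraw a module, which is documented as a new ``not valid``-coded
record starting on the withdrawal date (open-ended) — never by mutating
the original record.

Cohort sizes are exact by construction: for each module,
``round(opt_in_probability * n_patients)`` patients opt in, and
``round(withdrawal_probability * n_opted_in)`` of those later withdraw.
Which patients fall into each group is drawn from the seeded generator,
so a fixed seed reproduces the population byte-for-byte.

Alongside the records the generator emits its own ground truth: the
status it intends for every (patient, module, probe date), computed
directly from the generating events.  Probe dates bracket every period
boundary (±1 day) plus a mid-period date, so edge cases are hit by
construction.  This ground truth is the primary oracle for the
resolution engine.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

from .engine import max_capped_end
from .errors import ValidationError
from .model import (
    ConsentRecord,
    ConsentTemplate,
    PatientRef,
    StatusLabel,
    ValidityPeriod,
)
from .mappers import write_any
from .registry import CodeRegistry

__all__ = ["PopulationSpec", "ProbeTruth", "generate_population", "emit_documents"]

#: Synthetic patient-identifier namespace (2.999 = example OID arc).
PATIENT_ID_SYSTEM = "2.999.1"


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of a synthetic consent population.

    Defaults encode the reference scenario used throughout the test
    suite: 100 patients, 30% opt-in per module, one in six opted-in
    patients later withdrawing, five-year consent validity.
    """

    n_patients: int = 100
    template: ConsentTemplate | None = None  # None = bundled template
    opt_in_probability: float = 0.3
    withdrawal_probability: float = 1 / 6
    #: withdrawal happens this many days after the consent start (uniform)
    withdrawal_lag_days: tuple[int, int] = (30, 720)
    #: consent validity in years; the period end is start + years - 1 day
    period_years: int = 5
    #: enrollment dates drawn uniformly from this window
    enrollment_start: date = date(2018, 1, 1)
    enrollment_window_days: int = 730
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("opt_in_probability", "withdrawal_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if self.n_patients < 0:
            raise ValidationError("n_patients must be non-negative")


@dataclass(frozen=True)
class ProbeTruth:
    """Ground-truth status at one probe date, as intended by the generator."""

    patient: PatientRef
    policy_id: str
    at_date: date
    status: StatusLabel


def _probe_dates(
    start: date, end: date, withdrawal: date | None
) -> list[date]:
    day = timedelta(days=1)
    dates = {
        start - day, start, start + day,
        start + (end - start) // 2,  # fixed mid-period probe
        end - day, end, end + day,
    }
    if withdrawal is not None:
        dates.update({withdrawal - day, withdrawal, withdrawal + day})
    return sorted(dates)


def generate_population(
    spec: PopulationSpec, registry: CodeRegistry | None = None
) -> tuple[list[ConsentRecord], list[ProbeTruth]]:
    """Generate a seeded synthetic population.

    Returns the consent records (grouped into documents via
    ``document_id``) and the generator's own ground truth.  If no
    registry is given, one is built from the spec's template.
    """
    from .defaults import default_registry, default_template

    template = spec.template or default_template()
    if registry is None:
        registry = default_registry(template)

    rng = random.Random(spec.seed)
    n = spec.n_patients
    module_ids = template.module_ids

    # Exact per-module group sizes; membership drawn from the seeded rng
    # (template module order, so draws are reproducible).
    opted_in: dict[str, set[int]] = {}
    withdrawn: dict[str, set[int]] = {}
    for module_id in module_ids:
        k = round(spec.opt_in_probability * n)
        opted = set(rng.sample(range(n), k)) if k else set()
        opted_in[module_id] = opted
        wk = round(spec.withdrawal_probability * len(opted))
        withdrawn[module_id] = set(rng.sample(sorted(opted), wk)) if wk else set()

    records: list[ConsentRecord] = []
    truth: list[ProbeTruth] = []

    for i in range(n):  # patients outer, modules inner
        patient = PatientRef(
            identifier_value=f"patient{i:04d}", identifier_system=PATIENT_ID_SYSTEM
        )
        start = spec.enrollment_start + timedelta(
            days=rng.randint(0, spec.enrollment_window_days)
        )
        end = max_capped_end(start, spec.period_years)
        period = ValidityPeriod(start=start, end=end)
        doc_id = f"doc-{i:04d}-consent"

        for module_id in module_ids:
            label = (
                StatusLabel.VALID if i in opted_in[module_id] else StatusLabel.NOT_VALID
            )
            code = registry.code_for(module_id, template.template_version, label)
            records.append(
                ConsentRecord(
                    patient=patient, code=code, period=period, document_id=doc_id
                )
            )

            withdrawal_date: date | None = None
            if i in withdrawn[module_id]:
                lag = rng.randint(*spec.withdrawal_lag_days)
                withdrawal_date = start + timedelta(days=lag)
                not_valid = registry.code_for(
                    module_id, template.template_version, StatusLabel.NOT_VALID
                )
                records.append(
                    ConsentRecord(
                        patient=patient,
                        code=not_valid,
                        period=ValidityPeriod(start=withdrawal_date),
                        document_id=f"doc-{i:04d}-withdraw-{module_id}",
                    )
                )

            # ground truth straight from the generating events, independent
            # of the resolution engine
            for d in _probe_dates(start, end, withdrawal_date):
                if withdrawal_date is not None and d >= withdrawal_date:
                    expected = StatusLabel.NOT_VALID
                elif start <= d <= end:
                    expected = label
                else:
                    expected = StatusLabel.UNKNOWN
                truth.append(ProbeTruth(patient, module_id, d, expected))

    return records, truth


def emit_documents(
    records: list[ConsentRecord], dialect: str, out_dir: str | Path
) -> list[Path]:
    """Write records as one serialized document per generating event
    (grouped by ``document_id``).  Re-reading every emitted file
    reconstructs the record set exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups: dict[str, list[ConsentRecord]] = {}
    for record in records:
        key = record.document_id or f"doc-anon-{id(record)}"
        groups.setdefault(key, []).append(record)
    suffix = ".xml" if dialect == "bppc" else ".json"
    paths = []
    for doc_id, group in groups.items():
        path = out / f"{doc_id}{suffix}"
        path.write_text(write_any(group, dialect), encoding="utf-8")
        paths.append(path)
    return paths
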