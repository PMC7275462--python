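import random
from datetime import date, timedelta
from pathlib import Path

import pytest

from mii_consent import (
    CodeRegistry,
    ConsentRecord,
    PatientRef,
    StatusLabel,
    ValidityPeriod,
    default_registry,
    default_template,
)

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture()
def registry(template):
    return default_registry(template)


@pytest.fixture(scope="session")
def fhir_worked_example() -> str:
    return (FIXTURES / "fhir_r4_worked_example.json").read_text()


@pytest.fixture(scope="session")
def bppc_worked_example() -> str:
    return (FIXTURES / "bppc_worked_example.xml").read_text()


def make_random_records(
    rng: random.Random,
    registry: CodeRegistry,
    template,
    n: int,
    patient: PatientRef | None = None,
    shared_period: bool = False,
) -> list[ConsentRecord]:
    """Build n records for one random patient, with random module/status/
    period choices drawn from the seeded rng."""
    patient = patient or PatientRef(
        identifier_value=f"p{rng.randrange(10_000)}", identifier_system="2.999.1"
    )
    labels = list(StatusLabel)
    period = None
    records = []
    module_ids = rng.sample(template.module_ids, k=min(n, len(template.module_ids)))
    for i in range(n):
        module_id = module_ids[i % len(module_ids)]
        code = registry.code_for(
            module_id, template.template_version, rng.choice(labels)
        )
        if period is None or not shared_period:
            start = date(2018, 1, 1) + timedelta(days=rng.randrange(1500))
            end = (
                None
                if rng.random() < 0.3
                else start + timedelta(days=rng.randrange(1, 1800))
            )
            period = ValidityPeriod(start=start, end=end)
        records.append(ConsentRecord(patient=patient, code=code, period=period))
    return records
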