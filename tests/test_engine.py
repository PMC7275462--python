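"""Temporal resolution engine: effective status, cohorts, validation."""

import random
from datetime import date, datetime, timedelta, timezone

import pytest

from mii_consent import (
    ConsentRecord,
    ConsentStore,
    EngineConfig,
    PatientRef,
    StatusLabel,
    ValidityPeriod,
    cohort_query,
    effective_status,
    validate_record,
)
from mii_consent.engine import max_capped_end

_LABEL_RANK = {StatusLabel.NOT_VALID: 0, StatusLabel.UNKNOWN: 1, StatusLabel.VALID: 2}


def brute_force_status(records, patient, policy, at_date):
    """Independent oracle: filter by containment over the flat record
    list, sort by the documented tie-break, take the first."""
    covering = [
        r
        for r in records
        if r.patient == patient
        and r.code.policy == policy
        and r.period.start <= at_date
        and (r.period.end is None or at_date <= r.period.end)
    ]
    if not covering:
        return StatusLabel.UNKNOWN

    def sort_key(r):
        ts = r.recorded_at or datetime.min.replace(tzinfo=timezone.utc)
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        return (ts, r.period.start, -_LABEL_RANK[r.code.status])

    return sorted(covering, key=sort_key, reverse=True)[0].code.status


@pytest.fixture()
def valid_code(registry):
    return registry.code_for("mdat_collect_store_use", "1.6a", StatusLabel.VALID)


@pytest.fixture()
def not_valid_code(registry):
    return registry.code_for(
        "mdat_collect_store_use", "1.6a", StatusLabel.NOT_VALID
    )


class TestEffectiveStatus:
    def test_no_records_means_unknown(self, valid_code):
        store = ConsentStore()
        assert (
            effective_status(
                store, PatientRef("p"), valid_code.policy, date(2020, 1, 1)
            )
            is StatusLabel.UNKNOWN
        )

    def test_bounded_period_inside_valid_after_expiry_unknown(self, valid_code):
        patient = PatientRef("p")
        store = ConsentStore([
            ConsentRecord(
                patient=patient, code=valid_code,
                period=ValidityPeriod(date(2018, 10, 10), date(2023, 10, 9)),
            )
        ])
        assert (
            effective_status(store, patient, valid_code.policy, date(2020, 1, 1))
            is StatusLabel.VALID
        )
        # the day after expiry: documentation is no longer in effect
        assert (
            effective_status(store, patient, valid_code.policy, date(2023, 10, 10))
            is StatusLabel.UNKNOWN
        )
        # the day before the start likewise
        assert (
            effective_status(store, patient, valid_code.policy, date(2018, 10, 9))
            is StatusLabel.UNKNOWN
        )

    def test_withdrawal_as_new_record_wins_where_it_applies(
        self, valid_code, not_valid_code
    ):
        patient = PatientRef("p")
        store = ConsentStore([
            ConsentRecord(
                patient=patient, code=valid_code,
                period=ValidityPeriod(start=date(2018, 10, 10)),
            ),
            ConsentRecord(
                patient=patient, code=not_valid_code,
                period=ValidityPeriod(start=date(2020, 6, 1)),
            ),
        ])
        assert (
            effective_status(store, patient, valid_code.policy, date(2021, 1, 1))
            is StatusLabel.NOT_VALID
        )
        # before the withdrawal the original consent still applies
        assert (
            effective_status(store, patient, valid_code.policy, date(2019, 1, 1))
            is StatusLabel.VALID
        )

    def test_recorded_at_outranks_period_start(self, valid_code, not_valid_code):
        patient = PatientRef("p")
        store = ConsentStore([
            ConsentRecord(
                patient=patient, code=not_valid_code,
                period=ValidityPeriod(start=date(2020, 1, 1)),
                recorded_at=datetime(2022, 1, 1, tzinfo=timezone.utc),
            ),
            ConsentRecord(
                patient=patient, code=valid_code,
                period=ValidityPeriod(start=date(2021, 1, 1)),
                recorded_at=datetime(2021, 1, 1, tzinfo=timezone.utc),
            ),
        ])
        # later documentation wins although its period starts earlier
        assert (
            effective_status(store, patient, valid_code.policy, date(2021, 6, 1))
            is StatusLabel.NOT_VALID
        )

    def test_exact_tie_resolves_deny_biased(self, valid_code, not_valid_code):
        patient = PatientRef("p")
        period = ValidityPeriod(start=date(2020, 1, 1))
        store = ConsentStore([
            ConsentRecord(patient=patient, code=valid_code, period=period),
            ConsentRecord(patient=patient, code=not_valid_code, period=period),
        ])
        assert (
            effective_status(store, patient, valid_code.policy, date(2020, 6, 1))
            is StatusLabel.NOT_VALID
        )


def build_random_store(rng, registry, template, n_patients=8, n_records=40):
    patients = [PatientRef(f"p{i}") for i in range(n_patients)]
    policies = [
        registry.codes_for(m, template.template_version)[0].policy
        for m in template.module_ids
    ]
    records = []
    for _ in range(n_records):
        patient = rng.choice(patients)
        policy = rng.choice(policies)
        label = rng.choice(list(StatusLabel))
        code = registry.code_for(
            policy.policy_id, policy.template_version, label
        )
        start = date(2018, 1, 1) + timedelta(days=rng.randrange(1000))
        end = (
            None
            if rng.random() < 0.4
            else start + timedelta(days=rng.randrange(0, 1200))
        )
        recorded = (
            None
            if rng.random() < 0.5
            else datetime(2018, 1, 1, tzinfo=timezone.utc)
            + timedelta(hours=rng.randrange(40000))
        )
        records.append(
            ConsentRecord(
                patient=patient, code=code,
                period=ValidityPeriod(start=start, end=end),
                recorded_at=recorded,
            )
        )
    return records, patients, policies


class TestOracleEquivalence:
    def test_agrees_with_brute_force_on_randomized_queries(
        self, registry, template
    ):
        rng = random.Random(2024)
        checked = 0
        while checked < 10_000:
            records, patients, policies = build_random_store(rng, registry, template)
            store = ConsentStore(records)
            for _ in range(200):
                patient = rng.choice(patients)
                policy = rng.choice(policies)
                d = date(2018, 1, 1) + timedelta(days=rng.randrange(2500))
                assert effective_status(store, patient, policy, d) is (
                    brute_force_status(records, patient, policy, d)
                )
                checked += 1

    def test_insertion_order_does_not_matter(self, registry, template):
        rng = random.Random(55)
        records, patients, policies = build_random_store(rng, registry, template)
        shuffled = records[:]
        rng.shuffle(shuffled)
        a, b = ConsentStore(records), ConsentStore(shuffled)
        for patient in patients:
            for policy in policies:
                for offset in range(0, 2500, 97):
                    d = date(2018, 1, 1) + timedelta(days=offset)
                    assert effective_status(a, patient, policy, d) is (
                        effective_status(b, patient, policy, d)
                    )

    def test_three_cohorts_partition_patient_universe(self, registry, template):
        rng = random.Random(77)
        records, patients, policies = build_random_store(
            rng, registry, template, n_patients=20, n_records=80
        )
        store = ConsentStore(records)
        universe = set(store.patients)
        for policy in policies[:3]:
            for d in (date(2018, 6, 1), date(2020, 6, 1), date(2024, 6, 1)):
                cohorts = [
                    cohort_query(store, policy, d, label) for label in StatusLabel
                ]
                assert set().union(*cohorts) == universe
                total = sum(len(c) for c in cohorts)
                assert total == len(universe)  # pairwise disjoint

    def test_cohort_on_empty_store_is_empty(self, registry):
        policy = registry.codes_for("kvdat_retro_5y", "1.6a")[0].policy
        assert cohort_query(
            ConsentStore(), policy, date(2020, 1, 1), StatusLabel.VALID
        ) == set()


class TestValidateRecord:
    def make_insurance_record(self, registry, start, end):
        code = registry.code_for("kvdat_retrieve_5y", "1.6a", StatusLabel.VALID)
        return ConsentRecord(
            patient=PatientRef("p"), code=code,
            period=ValidityPeriod(start=start, end=end),
        )

    def test_worked_example_period_is_under_the_cap(self, registry, template):
        record = self.make_insurance_record(
            registry, date(2018, 10, 10), date(2023, 10, 9)
        )
        assert validate_record(record, template) == []

    def test_period_exceeding_five_years_violates(self, registry, template):
        record = self.make_insurance_record(
            registry, date(2018, 10, 10), date(2024, 10, 10)
        )
        violations = validate_record(record, template)
        assert [v.code for v in violations] == ["duration"]

    def test_one_day_over_the_cap_violates(self, registry, template):
        record = self.make_insurance_record(
            registry, date(2018, 10, 10), date(2023, 10, 10)
        )
        assert [v.code for v in validate_record(record, template)] == ["duration"]

    def test_open_ended_insurance_period_violates(self, registry, template):
        record = self.make_insurance_record(registry, date(2018, 10, 10), None)
        assert [v.code for v in validate_record(record, template)] == ["duration"]

    def test_non_insurance_module_has_no_cap(self, registry, template):
        code = registry.code_for("mdat_collect_store_use", "1.6a",
                                 StatusLabel.VALID)
        record = ConsentRecord(
            patient=PatientRef("p"), code=code,
            period=ValidityPeriod(start=date(2000, 1, 1)),  # open-ended
        )
        assert validate_record(record, template) == []

    def test_module_absent_from_template_version_violates(self, registry):
        from mii_consent import ConsentTemplate, Module

        other = ConsentTemplate("1.6a", ("s",), (Module("m_only", "", "s"),))
        code = registry.code_for("mdat_collect_store_use", "1.6a",
                                 StatusLabel.VALID)
        record = ConsentRecord(
            patient=PatientRef("p"), code=code,
            period=ValidityPeriod(start=date(2020, 1, 1), end=date(2020, 2, 1)),
        )
        assert [v.code for v in validate_record(record, other)] == [
            "template-mismatch"
        ]

    def test_cap_end_arithmetic_matches_worked_example(self):
        assert max_capped_end(date(2018, 10, 10), 5) == date(2023, 10, 9)
        # leap-day start
        assert max_capped_end(date(2020, 2, 29), 5) == date(2025, 2, 27)
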