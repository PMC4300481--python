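from datetime import date

import pytest

from smartscreen import CohortSpec, benchmark_fixture, default_ruleset, generate_cohort
from smartscreen.records import (Contact, MedicalHistory, PersonRecord, PhysicalExam,
                                 Sex, SmokingStatus)


@pytest.fixture(scope="session")
def ruleset():
    return default_ruleset()


@pytest.fixture(scope="session")
def benchmark():
    """The deterministic bundled 261-person benchmark scenario."""
    return benchmark_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortSpec(n=40, seed=7))


@pytest.fixture
def make_person():
    """Factory for a minimal valid person with overridable attributes."""

    def factory(person_id="P1", sex=Sex.male, birth=date(1975, 3, 10),
                exam=None, **kwargs):
        if exam is None:
            exam = PhysicalExam(date=date(2011, 5, 2), systolic=118, diastolic=76,
                                height=172.0, weight=70.0, waist=84.0)
        defaults = dict(
            person_id=person_id, name="Test Person", birth_date=birth, sex=sex,
            contact=Contact(email="p@example.org", phone="+98-900-0000001"),
            history=MedicalHistory(smoking=SmokingStatus.never),
            exams=[exam])
        defaults.update(kwargs)
        return PersonRecord(**defaults)

    return factory
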