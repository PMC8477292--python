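import numpy as np
import pytest

from hvec.data_model import (
    CATEGORIES,
    ClinicalRecord,
    Cohort,
    MedicalCode,
    Person,
    flag_ca,
)
from hvec.synthetic_cohort import GeneratorConfig, generate_cohort


def make_record(record_id="r0", person_id="p0", date=0, claim_type="outpatient",
                codes=(), care_site_type=0, care_site_specialization=0,
                care_site_rank=0, hospital_stay=0, costs=None,
                discharge_dead_or_critical=False):
    """Build a consistent ClinicalRecord (counts derived from codes)."""
    codes = [MedicalCode(c, v) if isinstance(c, str) else c
             for c, v in codes] if codes and isinstance(codes[0], tuple) else list(codes)
    counts = [sum(1 for c in codes if c.category == cat) for cat in CATEGORIES]
    rec = ClinicalRecord(
        record_id=record_id, person_id=person_id, date=date, claim_type=claim_type,
        codes=codes, care_site_type=care_site_type,
        care_site_specialization=care_site_specialization,
        care_site_rank=care_site_rank, hospital_stay=hospital_stay,
        costs=costs or [0.0] * 5, counts=counts,
        discharge_dead_or_critical=discharge_dead_or_critical,
    )
    rec.is_ca = flag_ca(rec)
    return rec


def make_person(person_id="p0", gender="female", birth_year=1950, records=()):
    return Person(person_id, gender, birth_year, list(records))


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-condition synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_persons=300, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    """A 2,000-person default-condition cohort for summary-level checks."""
    return generate_cohort(GeneratorConfig(n_persons=2000, seed=7))
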