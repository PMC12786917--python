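import numpy as np
import pytest

from endoquest import (
    Adjective, CoursePattern, Label, PainLocation, PatientRecord,
    SensoryItem, default_spec, generate,
)

_SYMPTOM_NRS = [
    ("dysmenorrhea", "dysmenorrhea_nrs"),
    ("cpp", "cpp_nrs"),
    ("dysuria", "dysuria_nrs"),
    ("dyschezia", "dyschezia_nrs"),
    ("dyspareunia", "dyspareunia_nrs"),
]


def random_record(rng: np.random.Generator, pid: str = "P1",
                  missing_rate: float = 0.2) -> PatientRecord:
    """A random but always-valid patient record."""

    def maybe(value):
        return None if rng.random() < missing_rate else value

    rec = PatientRecord(patient_id=pid)
    rec.label = maybe(Label.EMS if rng.random() < 0.5 else Label.NO_EMS)
    rec.age_yrs = maybe(float(rng.integers(18, 50)))
    rec.bmi = maybe(round(float(rng.uniform(17, 35)), 1))
    rec.smoker = maybe(bool(rng.random() < 0.2))
    rec.allergies = maybe(bool(rng.random() < 0.5))
    rec.analgesic_use = maybe(bool(rng.random() < 0.6))
    for sym, nrs in _SYMPTOM_NRS:
        present = bool(rng.random() < 0.5)
        setattr(rec, sym, maybe(present))
        v = int(rng.integers(1, 11)) if present else 0
        if getattr(rec, sym) is False:
            v = 0
        setattr(rec, nrs, maybe(v))
        # keep the symptom-absent => NRS 0 invariant
        if getattr(rec, sym) is False and getattr(rec, nrs) not in (None, 0):
            setattr(rec, nrs, 0)
    rec.obstipation = maybe(bool(rng.random() < 0.3))
    rec.diarrhea = maybe(bool(rng.random() < 0.3))
    rec.pain_before_menses = maybe(bool(rng.random() < 0.4))
    rec.pain_during_menses = maybe(bool(rng.random() < 0.5))
    rec.pain_after_menses = maybe(bool(rng.random() < 0.2))
    for adj in Adjective:
        rec.adjectives[adj] = maybe(bool(rng.random() < 0.4))
    for loc in PainLocation:
        rec.locations[loc] = maybe(bool(rng.random() < 0.3))
    rec.pain_now_nrs = maybe(int(rng.integers(0, 11)))
    rec.strongest_4wks_nrs = maybe(int(rng.integers(0, 11)))
    rec.average_4wks_nrs = maybe(int(rng.integers(0, 11)))
    rec.course_pattern = maybe(
        list(CoursePattern)[rng.integers(0, len(CoursePattern))])
    rec.radiating_pain = maybe(bool(rng.random() < 0.2))
    for s in SensoryItem:
        rec.sensory_items[s] = maybe(int(rng.integers(0, 6)))
    return rec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_cohort():
    """One calibrated synthetic cohort at the study size (n = 228)."""
    return generate(default_spec(), seed=123)


@pytest.fixture(scope="session")
def random_records():
    r = np.random.default_rng(7)
    return [random_record(r, pid=f"R{i}") for i in range(200)]
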