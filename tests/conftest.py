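from datetime import date, datetime

import pytest

from cbis.diary import (
    AssessmentRecord,
    IntakeEvent,
    LeakEvent,
    PatientDiary,
    PatientProfile,
    SleepRecord,
    TrainingRecord,
    VoidEvent,
)
from cbis.simulator import SimConfig, generate_cohort


def dt(day: int, hour: int, minute: int = 0, second: int = 0) -> datetime:
    """Shorthand timestamp inside a fixed reference week (2024-03-04 = Monday)."""
    return datetime(2024, 3, 3 + day, hour, minute, second)


@pytest.fixture
def profile() -> PatientProfile:
    return PatientProfile(patient_id="T001", age=66.0, bmi=24.0,
                          time_since_onset=90.0, qmax=18.0, qave=10.0,
                          residual_urine=30.0)


@pytest.fixture
def tiny_diary(profile) -> PatientDiary:
    """Hand-built 3-day diary (Mon-Wed) with every stream populated."""
    voids = []
    intakes = []
    sleep = []
    training = []
    for d in (1, 2, 3):
        voids += [
            VoidEvent(dt(d, 7, 30), volume=250.0, urgency_grade=1),
            VoidEvent(dt(d, 10, 0), volume=200.0, urgency_grade=3,
                      post_void_residual=50.0),
            VoidEvent(dt(d, 13, 0), volume=220.0, urgency_grade=0),
            VoidEvent(dt(d, 17, 0), volume=240.0, urgency_grade=4),
            VoidEvent(dt(d, 22, 30), volume=180.0, urgency_grade=1),
        ]
        intakes += [
            IntakeEvent(dt(d, 8, 0), volume=300.0, beverage_type="water"),
            IntakeEvent(dt(d, 9, 15), volume=200.0, beverage_type="coffee"),
            IntakeEvent(dt(d, 12, 30), volume=400.0, beverage_type="water"),
            IntakeEvent(dt(d, 19, 0), volume=300.0, beverage_type="tea"),
        ]
        sleep.append(SleepRecord(date=date(2024, 3, 3 + d),
                                 sleep_start=dt(d, 23, 0),
                                 sleep_end=dt(d + 1, 6, 30),
                                 night_arousals=2))
        for task in ("pfmt", "bladder_training"):
            training.append(TrainingRecord(date=date(2024, 3, 3 + d), task=task,
                                           prescribed=True, completed=True,
                                           feedback_score=7.0))
    # one nocturnal void (02:00 belongs to the previous diary day)
    voids.append(VoidEvent(dt(2, 2, 0), volume=150.0, urgency_grade=0))
    leaks = [LeakEvent(dt(1, 15, 0)), LeakEvent(dt(2, 16, 30))]
    assessments = [
        AssessmentRecord(date=date(2024, 3, 4), instrument="ICIQ_UI_SF", score=12.0),
        AssessmentRecord(date=date(2024, 3, 4), instrument="IPSS", score=15.0),
    ]
    return PatientDiary(profile=profile, voids=tuple(voids),
                        intakes=tuple(intakes), leaks=tuple(leaks),
                        sleep=tuple(sleep), training=tuple(training),
                        assessments=tuple(assessments))


@pytest.fixture(scope="session")
def small_cohort():
    """20 simulated patients, 3-day diaries (shared across tests)."""
    return generate_cohort(SimConfig(n_patients=20, days=3, seed=11))
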