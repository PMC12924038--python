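"""Domain model and lossless IO for bladder-diary event streams.

A bladder diary is a patient-maintained log of voids, fluid intake, leakage
episodes, sleep, activity and prescribed-training completion, kept for a
minimum of 3 days (International Continence Society convention).  Every other
stage of the pipeline — quality control, feature engineering, the decision
engine and the pre/post evaluation — consumes the :class:`PatientDiary`
container defined here.

Two on-disk dialects are supported and round-trip losslessly:

* a long-form delimited log, one event per row (``event_type`` column selects
  which value columns apply), and
* a structured JSON document mirroring the type structure.

Both carry a format-version marker.  See ``docs/data_formats.md``.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DiaryError",
    "DiaryFormatError",
    "DiaryInvariantError",
    "PatientProfile",
    "VoidEvent",
    "IntakeEvent",
    "LeakEvent",
    "SleepRecord",
    "ActivityRecord",
    "TrainingRecord",
    "AssessmentRecord",
    "PatientDiary",
    "RejectedRow",
    "ReadResult",
    "DayBundle",
    "read_diary",
    "write_diary",
    "day_partition",
    "night_window_for",
    "is_nocturnal",
    "MIN_DIARY_DAYS",
    "DEFAULT_DAY_BOUNDARY",
    "DEFAULT_NIGHT_WINDOW",
    "FORMAT_VERSION",
]

FORMAT_VERSION = 1

#: Minimum diary span admitted to modeling (days).
MIN_DIARY_DAYS = 3

#: Diary "day" boundary: events between midnight and 03:00 belong to the
#: preceding diary day (late-evening voids are part of that day's night).
DEFAULT_DAY_BOUNDARY = time(3, 0)

#: Fallback night window when no sleep record covers a night: 21:00-09:00.
#: Complements the 09:00-21:00 daytime convention used by the daytime
#: voiding-interval feature.
DEFAULT_NIGHT_WINDOW = (time(21, 0), time(9, 0))

BEVERAGE_TYPES = ("water", "tea", "coffee", "functional_drink", "other")
TRAINING_TASKS = ("pfmt", "bladder_training", "fluid_plan", "relaxation")
INSTRUMENTS = ("OABSS", "IPSS", "ICIQ_UI_SF", "SAS_SDS", "PSQI")
ACTIVITY_PERIODS = ("daytime", "nighttime")
ACTIVITY_INTENSITIES = ("light", "moderate", "vigorous")

#: Score ranges for the validated questionnaires (inclusive).
INSTRUMENT_RANGES = {
    "OABSS": (0.0, 15.0),
    "IPSS": (0.0, 35.0),
    "ICIQ_UI_SF": (0.0, 21.0),
    "SAS_SDS": (0.0, 100.0),
    "PSQI": (0.0, 21.0),
}


class DiaryError(Exception):
    """Base class for diary-layer errors."""


class DiaryFormatError(DiaryError):
    """File-level structural problem (bad header, unknown dialect/version)."""


class DiaryInvariantError(DiaryError):
    """A domain-type invariant is violated."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DiaryInvariantError(msg)


@dataclass(frozen=True)
class PatientProfile:
    patient_id: str
    sex: str = "male"
    age: float = 65.0
    bmi: float | None = None
    time_since_onset: float = 0.0  # days
    qmax: float | None = None  # mL/s
    qave: float | None = None  # mL/s
    residual_urine: float | None = None  # mL

    def __post_init__(self) -> None:
        _require(bool(self.patient_id), "patient_id must be non-empty")
        _require(18.0 <= self.age <= 100.0, f"age {self.age} outside [18, 100]")
        if self.bmi is not None:
            _require(10.0 <= self.bmi <= 60.0, f"bmi {self.bmi} outside [10, 60]")
        _require(self.time_since_onset >= 0, "time_since_onset must be >= 0")


@dataclass(frozen=True)
class VoidEvent:
    timestamp: datetime
    volume: float | None = None  # mL; may be missing before imputation
    flow_rate: float | None = None  # mL/min
    urgency_grade: int | None = None  # 0-5, patient-scored
    symptoms: frozenset[str] = frozenset()
    post_void_residual: float | None = None  # mL

    def __post_init__(self) -> None:
        if self.urgency_grade is not None:
            _require(self.urgency_grade in range(6), f"urgency_grade {self.urgency_grade} not in 0..5")
        if self.volume is not None:
            _require(self.volume >= 0, "void volume must be >= 0")
        if self.post_void_residual is not None:
            _require(self.post_void_residual >= 0, "post_void_residual must be >= 0")
        object.__setattr__(self, "symptoms", frozenset(self.symptoms))


@dataclass(frozen=True)
class IntakeEvent:
    timestamp: datetime
    volume: float | None = None  # mL; may be missing before imputation
    beverage_type: str | None = None

    def __post_init__(self) -> None:
        if self.volume is not None:
            _require(self.volume > 0, "intake volume must be > 0")
        if self.beverage_type is not None:
            _require(self.beverage_type in BEVERAGE_TYPES, f"unknown beverage_type {self.beverage_type!r}")


@dataclass(frozen=True)
class LeakEvent:
    timestamp: datetime
    count_weight: int = 1  # one episode per record by convention

    def __post_init__(self) -> None:
        _require(self.count_weight >= 1, "count_weight must be a positive integer")


@dataclass(frozen=True)
class SleepRecord:
    date: date
    sleep_start: datetime
    sleep_end: datetime
    night_arousals: int = 0

    def __post_init__(self) -> None:
        _require(self.sleep_end > self.sleep_start, "sleep_end must be after sleep_start")
        _require(self.night_arousals >= 0, "night_arousals must be >= 0")


@dataclass(frozen=True)
class ActivityRecord:
    interval_start: datetime
    interval_end: datetime
    period: str = "daytime"
    intensity: str = "light"
    steps: int | None = None

    def __post_init__(self) -> None:
        _require(self.interval_end > self.interval_start, "interval_end must be after interval_start")
        _require(self.period in ACTIVITY_PERIODS, f"unknown period {self.period!r}")
        _require(self.intensity in ACTIVITY_INTENSITIES, f"unknown intensity {self.intensity!r}")


@dataclass(frozen=True)
class TrainingRecord:
    date: date
    task: str
    prescribed: bool = True
    completed: bool = False
    feedback_score: float | None = None  # 0-10 perceived efficacy/difficulty
    abnormal_event: bool = False

    def __post_init__(self) -> None:
        _require(self.task in TRAINING_TASKS, f"unknown task {self.task!r}")
        _require(not (self.completed and not self.prescribed), "completed implies prescribed")
        if self.feedback_score is not None:
            _require(0.0 <= self.feedback_score <= 10.0, "feedback_score outside [0, 10]")


@dataclass(frozen=True)
class AssessmentRecord:
    date: date
    instrument: str
    score: float

    def __post_init__(self) -> None:
        _require(self.instrument in INSTRUMENTS, f"unknown instrument {self.instrument!r}")
        lo, hi = INSTRUMENT_RANGES[self.instrument]
        _require(lo <= self.score <= hi, f"{self.instrument} score {self.score} outside [{lo}, {hi}]")


def _sorted_by(items: Sequence, key) -> tuple:
    return tuple(sorted(items, key=key))


@dataclass(frozen=True)
class PatientDiary:
    """A patient's profile plus time-ordered event streams.

    Streams are sorted on construction; ``span_days`` is the inclusive
    calendar span of diary days covered (0 for an empty diary).  Diaries
    shorter than :data:`MIN_DIARY_DAYS` are representable but refused by the
    modeling gate (:meth:`admitted`).
    """

    profile: PatientProfile
    voids: tuple[VoidEvent, ...] = ()
    intakes: tuple[IntakeEvent, ...] = ()
    leaks: tuple[LeakEvent, ...] = ()
    sleep: tuple[SleepRecord, ...] = ()
    activity: tuple[ActivityRecord, ...] = ()
    training: tuple[TrainingRecord, ...] = ()
    assessments: tuple[AssessmentRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "voids", _sorted_by(self.voids, lambda e: e.timestamp))
        object.__setattr__(self, "intakes", _sorted_by(self.intakes, lambda e: e.timestamp))
        object.__setattr__(self, "leaks", _sorted_by(self.leaks, lambda e: e.timestamp))
        object.__setattr__(self, "sleep", _sorted_by(self.sleep, lambda r: r.date))
        object.__setattr__(self, "activity", _sorted_by(self.activity, lambda r: r.interval_start))
        object.__setattr__(self, "training", _sorted_by(self.training, lambda r: (r.date, r.task)))
        object.__setattr__(self, "assessments", _sorted_by(self.assessments, lambda r: (r.date, r.instrument)))

    # -- derived ---------------------------------------------------------

    def _all_dates(self) -> list[date]:
        days: list[date] = []
        days += [diary_day(e.timestamp, sleep=self.sleep) for e in self.voids]
        days += [diary_day(e.timestamp, sleep=self.sleep) for e in self.intakes]
        days += [diary_day(e.timestamp, sleep=self.sleep) for e in self.leaks]
        days += [r.date for r in self.sleep]
        days += [diary_day(r.interval_start, sleep=self.sleep) for r in self.activity]
        days += [r.date for r in self.training]
        days += [r.date for r in self.assessments]
        return days

    @property
    def span_days(self) -> int:
        days = self._all_dates()
        if not days:
            return 0
        return (max(days) - min(days)).days + 1

    @property
    def start_date(self) -> date | None:
        days = self._all_dates()
        return min(days) if days else None

    def admitted(self) -> bool:
        """True iff the diary meets the 3-day minimum for modeling."""
        return self.span_days >= MIN_DIARY_DAYS

    def n_events(self) -> int:
        """Timestamped event count (voids + intakes + leaks + activity)."""
        return len(self.voids) + len(self.intakes) + len(self.leaks) + len(self.activity)


# ---------------------------------------------------------------------------
# day / night conventions
# ---------------------------------------------------------------------------

def diary_day(ts: datetime, day_boundary: time = DEFAULT_DAY_BOUNDARY,
              sleep: Sequence[SleepRecord] = ()) -> date:
    """Diary day a timestamp belongs to.

    Events before the 03:00 boundary belong to the previous calendar day (its
    night).  When sleep records are available, an early-morning event still
    inside the previous day's recorded sleep interval also belongs to that
    previous diary day — a 05:30 nocturia episode is part of the night of the
    day before, not the following day's record.
    """
    shifted = ts - timedelta(hours=day_boundary.hour, minutes=day_boundary.minute)
    d = shifted.date()
    prev = d - timedelta(days=1)
    for rec in sleep:
        if rec.date == prev and rec.sleep_start <= ts < rec.sleep_end:
            return prev
    return d


def night_window_for(day: date, sleep: Sequence[SleepRecord]) -> tuple[datetime, datetime]:
    """Night interval for a diary day: the recorded sleep interval when one
    exists for that day, else the 21:00-09:00 fallback window."""
    for rec in sleep:
        if rec.date == day:
            return rec.sleep_start, rec.sleep_end
    start = datetime.combine(day, DEFAULT_NIGHT_WINDOW[0])
    end = datetime.combine(day + timedelta(days=1), DEFAULT_NIGHT_WINDOW[1])
    return start, end


def is_nocturnal(ts: datetime, sleep: Sequence[SleepRecord],
                 day_boundary: time = DEFAULT_DAY_BOUNDARY) -> bool:
    """Whether a timestamp falls in its diary day's night window (closed at
    the start, open at the end)."""
    day = diary_day(ts, day_boundary, sleep)
    start, end = night_window_for(day, sleep)
    return start <= ts < end


@dataclass(frozen=True)
class DayBundle:
    """All of one diary day's events (nocturnal voids flagged)."""

    date: date
    voids: tuple[VoidEvent, ...]
    nocturnal_flags: tuple[bool, ...]
    intakes: tuple[IntakeEvent, ...]
    leaks: tuple[LeakEvent, ...]
    activity: tuple[ActivityRecord, ...]
    sleep: tuple[SleepRecord, ...]
    training: tuple[TrainingRecord, ...]
    assessments: tuple[AssessmentRecord, ...]

    def n_events(self) -> int:
        return len(self.voids) + len(self.intakes) + len(self.leaks) + len(self.activity)


def day_partition(diary: PatientDiary,
                  day_boundary: time = DEFAULT_DAY_BOUNDARY) -> list[DayBundle]:
    """Partition a diary into per-day bundles.

    Every timestamped event is assigned to exactly one diary day (conservation:
    bundle sizes sum to the stream lengths); voids carry a nocturnal flag per
    the night-window convention.
    """
    if diary.span_days == 0:
        return []
    by_day: dict[date, dict[str, list]] = {}

    def slot(d: date) -> dict[str, list]:
        return by_day.setdefault(d, {k: [] for k in
                                      ("voids", "noct", "intakes", "leaks",
                                       "activity", "sleep", "training", "assessments")})

    for v in diary.voids:
        d = diary_day(v.timestamp, day_boundary, diary.sleep)
        s = slot(d)
        s["voids"].append(v)
        s["noct"].append(is_nocturnal(v.timestamp, diary.sleep, day_boundary))
    for e in diary.intakes:
        slot(diary_day(e.timestamp, day_boundary, diary.sleep))["intakes"].append(e)
    for e in diary.leaks:
        slot(diary_day(e.timestamp, day_boundary, diary.sleep))["leaks"].append(e)
    for a in diary.activity:
        slot(diary_day(a.interval_start, day_boundary, diary.sleep))["activity"].append(a)
    for r in diary.sleep:
        slot(r.date)["sleep"].append(r)
    for r in diary.training:
        slot(r.date)["training"].append(r)
    for r in diary.assessments:
        slot(r.date)["assessments"].append(r)

    return [
        DayBundle(
            date=d,
            voids=tuple(s["voids"]),
            nocturnal_flags=tuple(s["noct"]),
            intakes=tuple(s["intakes"]),
            leaks=tuple(s["leaks"]),
            activity=tuple(s["activity"]),
            sleep=tuple(s["sleep"]),
            training=tuple(s["training"]),
            assessments=tuple(s["assessments"]),
        )
        for d, s in sorted(by_day.items())
    ]


# ---------------------------------------------------------------------------
# IO — long-form delimited dialect
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "patient_id", "timestamp", "event_type",
    # void
    "volume", "flow_rate", "urgency_grade", "symptoms", "post_void_residual",
    # intake
    "beverage_type",
    # leak
    "count_weight",
    # sleep
    "date", "sleep_start", "sleep_end", "night_arousals",
    # activity
    "interval_start", "interval_end", "period", "intensity", "steps",
    # training
    "task", "prescribed", "completed", "feedback_score", "abnormal_event",
    # assessment
    "instrument", "score",
    # profile
    "sex", "age", "bmi", "time_since_onset", "qmax", "qave", "residual_urine",
]

_VERSION_MARKER = f"# cbis-diary v{FORMAT_VERSION}"


@dataclass(frozen=True)
class RejectedRow:
    line_no: int
    reason: str
    raw: str


@dataclass(frozen=True)
class ReadResult:
    diary: PatientDiary
    rejects: tuple[RejectedRow, ...]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, frozenset):
        return ";".join(sorted(x))
    if isinstance(x, datetime):
        return x.isoformat(sep="T", timespec="seconds")
    if isinstance(x, date):
        return x.isoformat()
    if isinstance(x, float) and math.isnan(x):
        return ""
    return str(x)


def _opt_float(s: str) -> float | None:
    return float(s) if s not in ("", None) else None


def _opt_int(s: str) -> int | None:
    return int(float(s)) if s not in ("", None) else None


def _bool(s: str) -> bool:
    return s.strip().lower() in ("true", "1", "yes")


def _parse_dt(s: str) -> datetime:
    return datetime.fromisoformat(s)


def _profile_row(p: PatientProfile) -> dict:
    return {
        "patient_id": p.patient_id, "event_type": "profile", "sex": p.sex,
        "age": _fmt(p.age), "bmi": _fmt(p.bmi),
        "time_since_onset": _fmt(p.time_since_onset),
        "qmax": _fmt(p.qmax), "qave": _fmt(p.qave),
        "residual_urine": _fmt(p.residual_urine),
    }


def _event_rows(diary: PatientDiary) -> Iterable[dict]:
    pid = diary.profile.patient_id
    yield _profile_row(diary.profile)
    for v in diary.voids:
        yield {"patient_id": pid, "event_type": "void", "timestamp": _fmt(v.timestamp),
               "volume": _fmt(v.volume), "flow_rate": _fmt(v.flow_rate),
               "urgency_grade": _fmt(v.urgency_grade), "symptoms": _fmt(v.symptoms),
               "post_void_residual": _fmt(v.post_void_residual)}
    for e in diary.intakes:
        yield {"patient_id": pid, "event_type": "intake", "timestamp": _fmt(e.timestamp),
               "volume": _fmt(e.volume), "beverage_type": _fmt(e.beverage_type)}
    for e in diary.leaks:
        yield {"patient_id": pid, "event_type": "leak", "timestamp": _fmt(e.timestamp),
               "count_weight": _fmt(e.count_weight)}
    for r in diary.sleep:
        yield {"patient_id": pid, "event_type": "sleep", "date": _fmt(r.date),
               "sleep_start": _fmt(r.sleep_start), "sleep_end": _fmt(r.sleep_end),
               "night_arousals": _fmt(r.night_arousals)}
    for a in diary.activity:
        yield {"patient_id": pid, "event_type": "activity",
               "interval_start": _fmt(a.interval_start), "interval_end": _fmt(a.interval_end),
               "period": a.period, "intensity": a.intensity, "steps": _fmt(a.steps)}
    for t in diary.training:
        yield {"patient_id": pid, "event_type": "training", "date": _fmt(t.date),
               "task": t.task, "prescribed": _fmt(t.prescribed), "completed": _fmt(t.completed),
               "feedback_score": _fmt(t.feedback_score), "abnormal_event": _fmt(t.abnormal_event)}
    for s in diary.assessments:
        yield {"patient_id": pid, "event_type": "assessment", "date": _fmt(s.date),
               "instrument": s.instrument, "score": _fmt(s.score)}


def _diary_to_json(diary: PatientDiary) -> dict:
    p = diary.profile
    return {
        "version": FORMAT_VERSION,
        "profile": {
            "patient_id": p.patient_id, "sex": p.sex, "age": p.age, "bmi": p.bmi,
            "time_since_onset": p.time_since_onset, "qmax": p.qmax, "qave": p.qave,
            "residual_urine": p.residual_urine,
        },
        "voids": [{"timestamp": _fmt(v.timestamp), "volume": v.volume,
                   "flow_rate": v.flow_rate, "urgency_grade": v.urgency_grade,
                   "symptoms": sorted(v.symptoms), "post_void_residual": v.post_void_residual}
                  for v in diary.voids],
        "intakes": [{"timestamp": _fmt(e.timestamp), "volume": e.volume,
                     "beverage_type": e.beverage_type} for e in diary.intakes],
        "leaks": [{"timestamp": _fmt(e.timestamp), "count_weight": e.count_weight}
                  for e in diary.leaks],
        "sleep": [{"date": _fmt(r.date), "sleep_start": _fmt(r.sleep_start),
                   "sleep_end": _fmt(r.sleep_end), "night_arousals": r.night_arousals}
                  for r in diary.sleep],
        "activity": [{"interval_start": _fmt(a.interval_start), "interval_end": _fmt(a.interval_end),
                      "period": a.period, "intensity": a.intensity, "steps": a.steps}
                     for a in diary.activity],
        "training": [{"date": _fmt(t.date), "task": t.task, "prescribed": t.prescribed,
                      "completed": t.completed, "feedback_score": t.feedback_score,
                      "abnormal_event": t.abnormal_event} for t in diary.training],
        "assessments": [{"date": _fmt(s.date), "instrument": s.instrument, "score": s.score}
                        for s in diary.assessments],
    }


def _diary_from_json(doc: dict) -> PatientDiary:
    if doc.get("version") != FORMAT_VERSION:
        raise DiaryFormatError(f"unsupported diary format version {doc.get('version')!r}")
    pr = doc["profile"]
    profile = PatientProfile(
        patient_id=pr["patient_id"], sex=pr.get("sex", "male"), age=pr["age"],
        bmi=pr.get("bmi"), time_since_onset=pr.get("time_since_onset", 0.0),
        qmax=pr.get("qmax"), qave=pr.get("qave"), residual_urine=pr.get("residual_urine"))
    return PatientDiary(
        profile=profile,
        voids=tuple(VoidEvent(timestamp=_parse_dt(v["timestamp"]), volume=v.get("volume"),
                              flow_rate=v.get("flow_rate"), urgency_grade=v.get("urgency_grade"),
                              symptoms=frozenset(v.get("symptoms", ())),
                              post_void_residual=v.get("post_void_residual"))
                    for v in doc.get("voids", ())),
        intakes=tuple(IntakeEvent(timestamp=_parse_dt(e["timestamp"]), volume=e.get("volume"),
                                  beverage_type=e.get("beverage_type"))
                      for e in doc.get("intakes", ())),
        leaks=tuple(LeakEvent(timestamp=_parse_dt(e["timestamp"]),
                              count_weight=e.get("count_weight", 1))
                    for e in doc.get("leaks", ())),
        sleep=tuple(SleepRecord(date=date.fromisoformat(r["date"]),
                                sleep_start=_parse_dt(r["sleep_start"]),
                                sleep_end=_parse_dt(r["sleep_end"]),
                                night_arousals=r.get("night_arousals", 0))
                    for r in doc.get("sleep", ())),
        activity=tuple(ActivityRecord(interval_start=_parse_dt(a["interval_start"]),
                                      interval_end=_parse_dt(a["interval_end"]),
                                      period=a.get("period", "daytime"),
                                      intensity=a.get("intensity", "light"),
                                      steps=a.get("steps"))
                       for a in doc.get("activity", ())),
        training=tuple(TrainingRecord(date=date.fromisoformat(t["date"]), task=t["task"],
                                      prescribed=t.get("prescribed", True),
                                      completed=t.get("completed", False),
                                      feedback_score=t.get("feedback_score"),
                                      abnormal_event=t.get("abnormal_event", False))
                       for t in doc.get("training", ())),
        assessments=tuple(AssessmentRecord(date=date.fromisoformat(s["date"]),
                                           instrument=s["instrument"], score=s["score"])
                          for s in doc.get("assessments", ())),
    )


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "json"):
            raise DiaryFormatError(f"unknown dialect {dialect!r}")
        return dialect
    if path.suffix.lower() == ".json":
        return "json"
    return "csv"


def write_diary(diary: PatientDiary, path: str | Path, dialect: str | None = None) -> None:
    """Serialize a diary; refuses diaries violating type invariants.

    ``read_diary(write_diary(d))`` reproduces ``d`` field-for-field.
    """
    if not isinstance(diary, PatientDiary):
        raise DiaryInvariantError("write_diary expects a PatientDiary")
    path = Path(path)
    if _infer_dialect(path, dialect) == "json":
        path.write_text(json.dumps(_diary_to_json(diary), indent=1))
        return
    with open(path, "w", newline="") as fh:
        fh.write(_VERSION_MARKER + "\n")
        writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS, restval="")
        writer.writeheader()
        for row in _event_rows(diary):
            writer.writerow(row)


_ROW_TIMESTAMP_KEY = {
    "void": "timestamp", "intake": "timestamp", "leak": "timestamp",
    "sleep": "date", "activity": "interval_start",
    "training": "date", "assessment": "date",
}


def read_diary(path: str | Path, dialect: str | None = None) -> ReadResult:
    """Parse one patient's diary file.

    Unparseable rows are collected into a rejects report (with line number and
    reason), never silently dropped; exact duplicates — same
    (patient_id, timestamp, event kind) — are removed as diary re-submissions,
    each recorded as a reject with reason ``"duplicate"``.
    """
    path = Path(path)
    if not path.exists():
        raise DiaryFormatError(f"no such file: {path}")
    if _infer_dialect(path, dialect) == "json":
        return ReadResult(diary=_diary_from_json(json.loads(path.read_text())), rejects=())

    rejects: list[RejectedRow] = []
    profile: PatientProfile | None = None
    streams: dict[str, list] = {k: [] for k in
                                ("void", "intake", "leak", "sleep", "activity",
                                 "training", "assessment")}
    seen: set[tuple] = set()

    with open(path, newline="") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("# cbis-diary v"):
            raise DiaryFormatError("missing format-version marker line")
        if first.strip() != _VERSION_MARKER:
            raise DiaryFormatError(f"unsupported format version line {first!r}")
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(("patient_id", "event_type")) <= set(reader.fieldnames):
            raise DiaryFormatError("malformed header: need patient_id and event_type columns")
        for line_no, row in enumerate(reader, start=3):
            raw = ",".join((row.get(c) or "") for c in reader.fieldnames)
            etype = (row.get("event_type") or "").strip()
            try:
                if etype == "profile":
                    profile = PatientProfile(
                        patient_id=row["patient_id"], sex=row.get("sex") or "male",
                        age=float(row["age"]), bmi=_opt_float(row.get("bmi", "")),
                        time_since_onset=_opt_float(row.get("time_since_onset", "")) or 0.0,
                        qmax=_opt_float(row.get("qmax", "")), qave=_opt_float(row.get("qave", "")),
                        residual_urine=_opt_float(row.get("residual_urine", "")))
                    continue
                if etype not in streams:
                    raise DiaryFormatError(f"unknown event_type {etype!r}")
                key_field = _ROW_TIMESTAMP_KEY[etype]
                # dedup identity = (patient, timestamp, event kind); kind is
                # refined by task/instrument so distinct same-day records of
                # different tasks or scales are not conflated
                kind: tuple = (etype,)
                if etype == "training":
                    kind = (etype, row.get("task"))
                elif etype == "assessment":
                    kind = (etype, row.get("instrument"))
                key = (row["patient_id"], row.get(key_field, ""), kind)
                if key in seen:
                    rejects.append(RejectedRow(line_no, "duplicate", raw))
                    continue
                seen.add(key)
                if etype == "void":
                    streams["void"].append(VoidEvent(
                        timestamp=_parse_dt(row["timestamp"]), volume=_opt_float(row.get("volume", "")),
                        flow_rate=_opt_float(row.get("flow_rate", "")),
                        urgency_grade=_opt_int(row.get("urgency_grade", "")),
                        symptoms=frozenset(s for s in (row.get("symptoms") or "").split(";") if s),
                        post_void_residual=_opt_float(row.get("post_void_residual", ""))))
                elif etype == "intake":
                    streams["intake"].append(IntakeEvent(
                        timestamp=_parse_dt(row["timestamp"]), volume=_opt_float(row.get("volume", "")),
                        beverage_type=(row.get("beverage_type") or None)))
                elif etype == "leak":
                    streams["leak"].append(LeakEvent(
                        timestamp=_parse_dt(row["timestamp"]),
                        count_weight=_opt_int(row.get("count_weight", "")) or 1))
                elif etype == "sleep":
                    streams["sleep"].append(SleepRecord(
                        date=date.fromisoformat(row["date"]),
                        sleep_start=_parse_dt(row["sleep_start"]),
                        sleep_end=_parse_dt(row["sleep_end"]),
                        night_arousals=_opt_int(row.get("night_arousals", "")) or 0))
                elif etype == "activity":
                    streams["activity"].append(ActivityRecord(
                        interval_start=_parse_dt(row["interval_start"]),
                        interval_end=_parse_dt(row["interval_end"]),
                        period=row.get("period") or "daytime",
                        intensity=row.get("intensity") or "light",
                        steps=_opt_int(row.get("steps", ""))))
                elif etype == "training":
                    streams["training"].append(TrainingRecord(
                        date=date.fromisoformat(row["date"]), task=row["task"],
                        prescribed=_bool(row.get("prescribed", "true")),
                        completed=_bool(row.get("completed", "false")),
                        feedback_score=_opt_float(row.get("feedback_score", "")),
                        abnormal_event=_bool(row.get("abnormal_event", "false"))))
                elif etype == "assessment":
                    streams["assessment"].append(AssessmentRecord(
                        date=date.fromisoformat(row["date"]), instrument=row["instrument"],
                        score=float(row["score"])))
            except DiaryFormatError:
                raise
            except (KeyError, ValueError, DiaryInvariantError) as exc:
                rejects.append(RejectedRow(line_no, f"{type(exc).__name__}: {exc}", raw))

    if profile is None:
        if any(streams.values()) or rejects:
            raise DiaryFormatError("no profile row in diary file")
        # degenerate input: valid header, no rows at all -> empty diary
        profile = PatientProfile(patient_id="unknown")
    diary = PatientDiary(
        profile=profile,
        voids=tuple(streams["void"]), intakes=tuple(streams["intake"]),
        leaks=tuple(streams["leak"]), sleep=tuple(streams["sleep"]),
        activity=tuple(streams["activity"]), training=tuple(streams["training"]),
        assessments=tuple(streams["assessment"]))
    return ReadResult(diary=diary, rejects=tuple(rejects))


def replace_streams(diary: PatientDiary, **kwargs) -> PatientDiary:
    """Functional update helper (streams are immutable tuples)."""
    return replace(diary, **kwargs)
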