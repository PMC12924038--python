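"""Behavioral feature engineering: the 29-slot patient snapshot.

Features span six categories — basic profile, urinary behavior, drinking
behavior, activity/sleep interaction, validated scale scores, and system
interaction/adherence.  The engineered constructions (daytime voiding
interval, nocturnal polyuria ratio, urgency event frequency, effective
voiding rate, nocturia–arousal index, irritant beverage ratio,
workday–weekend pattern difference, post-exercise urgency marker, fluid–void
temporal association, PFMT adherence decay) are implemented as standalone
operations and assembled by :func:`build_feature_vector`.

A slot whose construction is undefined on the available data (e.g. too few
qualifying voids) carries NaN and propagates as missing.

Also here: Pearson-collinearity pruning (|r| > 0.9, later feature in
canonical order dropped) and the seeded stratified 70/15/15 split preserving
leakage-severity × adherence strata.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diary import PatientDiary, day_partition, diary_day, is_nocturnal
from .preprocessing import QCReport, align_intake_void

__all__ = [
    "FEATURE_SCHEMA",
    "FEATURE_NAMES",
    "FeatureVector",
    "SplitAssignment",
    "URGENCY_THRESHOLD",
    "DAYTIME_WINDOW",
    "daytime_mean_voiding_interval",
    "nocturnal_polyuria_ratio",
    "urgency_event_frequency",
    "effective_voiding_rate",
    "nocturia_arousal_index",
    "irritant_beverage_ratio",
    "workday_weekend_interval_diff",
    "postexercise_urgency_marker",
    "fluid_void_association_index",
    "pfmt_adherence_decay_rate",
    "build_feature_vector",
    "feature_matrix",
    "prune_collinear",
    "stratified_split",
    "leakage_band",
    "adherence_bands",
]

#: A void "with urgency" has urgency grade >= this cut on the 0-5 scale.
URGENCY_THRESHOLD = 3

#: Daytime window for the daytime voiding-interval feature: 09:00-21:00.
DAYTIME_WINDOW = (time(9, 0), time(21, 0))

#: Post-exercise urgency look-ahead (minutes, closed boundary).
POSTEXERCISE_WINDOW_MIN = 30.0

#: Canonical feature order (pruning ties resolve by this order).
FEATURE_SCHEMA: tuple[tuple[str, str], ...] = (
    # basic information (profile passthroughs)
    ("age", "basic"),
    ("bmi", "basic"),
    ("qmax", "basic"),
    ("qave", "basic"),
    ("residual_urine", "basic"),
    # urinary behavior
    ("daily_void_count", "urinary"),
    ("nocturia_count", "urinary"),
    ("nocturia_volume", "urinary"),
    ("mean_voiding_interval", "urinary"),
    ("daytime_mean_voiding_interval", "urinary"),
    ("nocturnal_polyuria_ratio", "urinary"),
    ("urgency_event_frequency", "urinary"),
    ("effective_voiding_rate", "urinary"),
    ("workday_weekend_interval_diff", "urinary"),
    # drinking behavior
    ("daily_intake_volume", "drinking"),
    ("irritant_beverage_ratio", "drinking"),
    ("fluid_void_association_index", "drinking"),
    # daily activity and sleep
    ("nocturia_arousal_index", "activity_sleep"),
    ("postexercise_urgency_marker", "activity_sleep"),
    # specialty scales
    ("oabss_score", "scales"),
    ("ipss_score", "scales"),
    ("iciq_ui_sf_score", "scales"),
    ("sas_sds_score", "scales"),
    ("psqi_score", "scales"),
    # system interaction and training feedback
    ("completion_record_rate", "interaction"),
    ("feedback_score_mean", "interaction"),
    ("abnormal_event_count", "interaction"),
    ("usage_frequency", "interaction"),
    ("pfmt_adherence_decay_rate", "interaction"),
)

FEATURE_NAMES: tuple[str, ...] = tuple(name for name, _ in FEATURE_SCHEMA)
assert len(FEATURE_NAMES) == 29

UNDEFINED = float("nan")


@dataclass(frozen=True)
class FeatureVector:
    """29 named numeric slots plus window metadata; NaN marks undefined."""

    patient_id: str
    values: Mapping[str, float]
    window_start: date | None
    span_days: int

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            raise ValueError("feature vector must carry exactly the 29 schema slots, in order")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def defined(self, name: str) -> bool:
        return not math.isnan(self.values[name])

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.values), name=self.patient_id)


# ---------------------------------------------------------------------------
# engineered constructions
# ---------------------------------------------------------------------------

def _minutes(a: datetime, b: datetime) -> float:
    return (b - a).total_seconds() / 60.0


def _in_daytime(ts: datetime) -> bool:
    return DAYTIME_WINDOW[0] <= ts.time() < DAYTIME_WINDOW[1]


def daytime_mean_voiding_interval(diary: PatientDiary,
                                  days: Iterable[date] | None = None) -> float:
    """Mean gap (minutes) between successive voids inside 09:00-21:00.

    Gaps count only when both endpoints fall inside the daytime window on the
    same calendar day; fewer than 2 qualifying voids -> NaN.
    """
    wanted = set(days) if days is not None else None
    by_day: dict[date, list[datetime]] = {}
    for v in diary.voids:
        if _in_daytime(v.timestamp):
            d = v.timestamp.date()
            if wanted is None or d in wanted:
                by_day.setdefault(d, []).append(v.timestamp)
    gaps = []
    for ts in by_day.values():
        ts.sort()
        gaps.extend(_minutes(a, b) for a, b in zip(ts, ts[1:]))
    return float(np.mean(gaps)) if gaps else UNDEFINED


def nocturnal_polyuria_ratio(diary: PatientDiary, day: date) -> float:
    """Nocturnal urine volume over 24-hour urine volume x 100 (percent)."""
    total = 0.0
    nocturnal = 0.0
    seen = False
    for v in diary.voids:
        if v.volume is None or diary_day(v.timestamp, sleep=diary.sleep) != day:
            continue
        seen = True
        total += v.volume
        if is_nocturnal(v.timestamp, diary.sleep):
            nocturnal += v.volume
    if not seen or total == 0.0:
        return UNDEFINED
    return 100.0 * nocturnal / total


def urgency_event_frequency(diary: PatientDiary, window_days: int = 7) -> float:
    """Fraction of voids with urgency (grade >= 3) over the trailing window."""
    if not diary.voids:
        return UNDEFINED
    end = max(v.timestamp for v in diary.voids)
    start = end - timedelta(days=window_days)
    in_window = [v for v in diary.voids if v.timestamp > start]
    if not in_window:
        return UNDEFINED
    urgent = sum(1 for v in in_window
                 if v.urgency_grade is not None and v.urgency_grade >= URGENCY_THRESHOLD)
    return urgent / len(in_window)


def effective_voiding_rate(diary: PatientDiary, day: date | None = None) -> float:
    """Mean of volume / (volume + post-void residual) x 100 over voids with a
    residual measurement — the bladder-emptying efficiency."""
    ratios = []
    for v in diary.voids:
        if v.post_void_residual is None or v.volume is None:
            continue
        if day is not None and diary_day(v.timestamp, sleep=diary.sleep) != day:
            continue
        denom = v.volume + v.post_void_residual
        if denom > 0:
            ratios.append(100.0 * v.volume / denom)
        elif v.post_void_residual == 0:
            ratios.append(100.0)
    return float(np.mean(ratios)) if ratios else UNDEFINED


def nocturia_arousal_index(diary: PatientDiary, day: date) -> float:
    """Nocturnal void episodes over night arousals for one diary day.

    Distinguishes pure nocturia (index near 1) from sleep disruption without
    voiding; undefined when no sleep record or zero recorded arousals.
    """
    rec = next((r for r in diary.sleep if r.date == day), None)
    if rec is None or rec.night_arousals < 1:
        return UNDEFINED
    n_noct = sum(1 for v in diary.voids
                 if diary_day(v.timestamp, sleep=diary.sleep) == day
                 and is_nocturnal(v.timestamp, diary.sleep))
    return n_noct / rec.night_arousals


def irritant_beverage_ratio(diary: PatientDiary, day: date | None = None) -> float:
    """Coffee + tea intake over total intake x 100 (percent)."""
    total = 0.0
    irritant = 0.0
    for e in diary.intakes:
        if e.volume is None:
            continue
        if day is not None and diary_day(e.timestamp, sleep=diary.sleep) != day:
            continue
        total += e.volume
        if e.beverage_type in ("coffee", "tea"):
            irritant += e.volume
    if total <= 0:
        return UNDEFINED
    return 100.0 * irritant / total


def _mean_interval_over(days_ts: dict[date, list[datetime]]) -> float:
    gaps = []
    for ts in days_ts.values():
        ts.sort()
        gaps.extend(_minutes(a, b) for a, b in zip(ts, ts[1:]))
    return float(np.mean(gaps)) if gaps else UNDEFINED


def workday_weekend_interval_diff(diary: PatientDiary) -> float:
    """Mean weekend voiding interval minus mean workday voiding interval
    (minutes, signed); undefined unless both sides have >= 2 voids a day."""
    weekend: dict[date, list[datetime]] = {}
    workday: dict[date, list[datetime]] = {}
    for v in diary.voids:
        d = diary_day(v.timestamp, sleep=diary.sleep)
        target = weekend if d.weekday() >= 5 else workday
        target.setdefault(d, []).append(v.timestamp)
    we = _mean_interval_over(weekend)
    wo = _mean_interval_over(workday)
    if math.isnan(we) or math.isnan(wo):
        return UNDEFINED
    return we - wo


def postexercise_urgency_marker(diary: PatientDiary, day: date | None = None) -> float:
    """1.0 iff an urgency-grade >= 3 void occurs within 30 minutes (closed
    boundary) after the end of a vigorous activity interval; else 0.0."""
    vigorous_ends = [a.interval_end for a in diary.activity
                     if a.intensity == "vigorous"
                     and (day is None or diary_day(a.interval_start, sleep=diary.sleep) == day)]
    if not vigorous_ends:
        return 0.0
    for v in diary.voids:
        if v.urgency_grade is None or v.urgency_grade < URGENCY_THRESHOLD:
            continue
        for end in vigorous_ends:
            lag = _minutes(end, v.timestamp)
            if 0.0 <= lag <= POSTEXERCISE_WINDOW_MIN:
                return 1.0
    return 0.0


def fluid_void_association_index(diary: PatientDiary, window: float = 60.0) -> float:
    """Fraction of voids preceded by an intake within the alignment window."""
    if not diary.voids:
        return UNDEFINED
    pairs = align_intake_void(diary, window=window)
    paired_voids = {p.void_index for p in pairs}
    return len(paired_voids) / len(diary.voids)


def pfmt_adherence_decay_rate(diary: PatientDiary) -> float:
    """Adherence rate over the last 3 diary days over adherence rate in week 1.

    Adherence rate = completed / prescribed PFMT tasks in the window.
    Requires >= 10 days of training records so the two windows are distinct;
    zero week-1 prescriptions (or zero week-1 rate) -> undefined.
    """
    pfmt = [t for t in diary.training if t.task == "pfmt"]
    if not pfmt:
        return UNDEFINED
    days = sorted({t.date for t in diary.training})
    if len(days) < 10:
        return UNDEFINED
    first = days[0]
    week1 = [t for t in pfmt if (t.date - first).days < 7]
    last = days[-1]
    last3 = [t for t in pfmt if (last - t.date).days < 3]
    w1_presc = sum(1 for t in week1 if t.prescribed)
    if w1_presc == 0:
        return UNDEFINED
    w1_rate = sum(1 for t in week1 if t.completed) / w1_presc
    if w1_rate == 0:
        return UNDEFINED
    l3_presc = sum(1 for t in last3 if t.prescribed)
    if l3_presc == 0:
        return UNDEFINED
    l3_rate = sum(1 for t in last3 if t.completed) / l3_presc
    return l3_rate / w1_rate


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _mean_defined(values: Iterable[float]) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return float(np.mean(vals)) if vals else UNDEFINED


def _latest_score(diary: PatientDiary, instrument: str) -> float:
    scores = [a for a in diary.assessments if a.instrument == instrument]
    return scores[-1].score if scores else UNDEFINED


def build_feature_vector(diary: PatientDiary, qc: QCReport) -> FeatureVector:
    """Assemble the full 29-slot snapshot for one QC-retained patient.

    Refuses excluded patients; slots whose construction is undefined on the
    available streams carry NaN, the rest are populated deterministically.
    """
    if qc.excluded:
        raise ValueError(f"patient {qc.patient_id} was excluded by the QC gate "
                         f"({', '.join(qc.exclusion_reasons)})")
    bundles = day_partition(diary)
    n_days = max(diary.span_days, 1)
    p = diary.profile

    noct_counts = []
    noct_volumes = []
    for b in bundles:
        noct = [v for v, f in zip(b.voids, b.nocturnal_flags) if f]
        noct_counts.append(len(noct))
        noct_volumes.append(sum(v.volume or 0.0 for v in noct))

    vols = [v.volume for v in diary.voids if v.volume is not None]
    all_ts = [v.timestamp for v in diary.voids]
    all_gaps = [_minutes(a, b) for a, b in zip(all_ts, all_ts[1:])]
    intake_total = sum(e.volume for e in diary.intakes if e.volume is not None)

    prescribed = sum(1 for t in diary.training if t.prescribed)
    completed = sum(1 for t in diary.training if t.completed)
    feedback = [t.feedback_score for t in diary.training if t.feedback_score is not None]
    n_entries = (len(diary.voids) + len(diary.intakes) + len(diary.leaks)
                 + len(diary.training))

    values: dict[str, float] = {
        "age": float(p.age),
        "bmi": p.bmi if p.bmi is not None else UNDEFINED,
        "qmax": p.qmax if p.qmax is not None else UNDEFINED,
        "qave": p.qave if p.qave is not None else UNDEFINED,
        "residual_urine": p.residual_urine if p.residual_urine is not None else UNDEFINED,
        "daily_void_count": len(diary.voids) / n_days if diary.voids else UNDEFINED,
        "nocturia_count": float(np.mean(noct_counts)) if bundles else UNDEFINED,
        "nocturia_volume": float(np.mean(noct_volumes)) if bundles else UNDEFINED,
        "mean_voiding_interval": float(np.mean(all_gaps)) if all_gaps else UNDEFINED,
        "daytime_mean_voiding_interval": daytime_mean_voiding_interval(diary),
        "nocturnal_polyuria_ratio": _mean_defined(
            nocturnal_polyuria_ratio(diary, b.date) for b in bundles),
        "urgency_event_frequency": urgency_event_frequency(diary),
        "effective_voiding_rate": effective_voiding_rate(diary),
        "workday_weekend_interval_diff": workday_weekend_interval_diff(diary),
        "daily_intake_volume": intake_total / n_days if diary.intakes else UNDEFINED,
        "irritant_beverage_ratio": irritant_beverage_ratio(diary),
        "fluid_void_association_index": fluid_void_association_index(diary),
        "nocturia_arousal_index": _mean_defined(
            nocturia_arousal_index(diary, b.date) for b in bundles),
        "postexercise_urgency_marker": postexercise_urgency_marker(diary),
        "oabss_score": _latest_score(diary, "OABSS"),
        "ipss_score": _latest_score(diary, "IPSS"),
        "iciq_ui_sf_score": _latest_score(diary, "ICIQ_UI_SF"),
        "sas_sds_score": _latest_score(diary, "SAS_SDS"),
        "psqi_score": _latest_score(diary, "PSQI"),
        "completion_record_rate": completed / prescribed if prescribed else UNDEFINED,
        "feedback_score_mean": float(np.mean(feedback)) if feedback else UNDEFINED,
        "abnormal_event_count": float(sum(1 for t in diary.training if t.abnormal_event)),
        "usage_frequency": n_entries / n_days,
        "pfmt_adherence_decay_rate": pfmt_adherence_decay_rate(diary),
    }
    ordered = {name: float(values[name]) for name in FEATURE_NAMES}
    return FeatureVector(patient_id=p.patient_id, values=ordered,
                         window_start=diary.start_date, span_days=diary.span_days)


def feature_matrix(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a patients x features DataFrame."""
    return pd.DataFrame([fv.as_series() for fv in vectors])


# ---------------------------------------------------------------------------
# collinearity pruning and stratified splitting
# ---------------------------------------------------------------------------

def prune_collinear(matrix: pd.DataFrame, threshold: float = 0.9
                    ) -> tuple[list[str], dict[str, str]]:
    """Drop collinear features: greedy scan in canonical column order.

    For each pair with |Pearson r| > threshold the later column is dropped;
    zero-variance columns are dropped with reason "degenerate".  Returns
    (retained names, {dropped name: reason}); no retained pair exceeds the
    threshold.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 patients to estimate correlations")
    retained: list[str] = []
    dropped: dict[str, str] = {}
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        obs = x[~np.isnan(x)]
        if obs.size < 3 or np.std(obs) == 0:
            dropped[col] = "degenerate"
            continue
        clash = None
        for kept in retained:
            pair = matrix[[kept, col]].dropna()
            if len(pair) < 3:
                continue
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(pair[kept], pair[col])[0, 1]
            if not np.isnan(r) and abs(r) > threshold:
                clash = kept
                break
        if clash is None:
            retained.append(col)
        else:
            dropped[col] = f"collinear_with:{clash}"
    return retained, dropped


@dataclass(frozen=True)
class SplitAssignment:
    partition: Mapping[str, str]  # patient_id -> train | validation | test
    strata: Mapping[str, str]  # patient_id -> stratum label

    def ids(self, part: str) -> list[str]:
        return [pid for pid, p in self.partition.items() if p == part]


def leakage_band(mean_daily_leaks: float) -> str:
    """Leakage-severity band by daily episodes: 0, 1-2, 3-7, >7."""
    if mean_daily_leaks <= 0:
        return "leak:0"
    if mean_daily_leaks <= 2:
        return "leak:1-2"
    if mean_daily_leaks <= 7:
        return "leak:3-7"
    return "leak:>7"


def adherence_bands(rates: Mapping[str, float]) -> dict[str, str]:
    """Adherence bands by cohort completion-rate tertiles."""
    vals = np.array([v for v in rates.values() if not math.isnan(v)], dtype=float)
    if vals.size == 0:
        return {pid: "adh:mid" for pid in rates}
    lo, hi = np.percentile(vals, [100 / 3, 200 / 3])
    out = {}
    for pid, v in rates.items():
        if math.isnan(v) or v <= lo:
            out[pid] = "adh:low"
        elif v <= hi:
            out[pid] = "adh:mid"
        else:
            out[pid] = "adh:high"
    return out


def stratified_split(patient_ids: Sequence[str],
                     strata: Mapping[str, str],
                     fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                     seed: int = 0) -> SplitAssignment:
    """Seeded stratified train/validation/test split.

    Within each stratum, patients are shuffled deterministically and allocated
    by largest-remainder rounding of the target fractions; strata smaller than
    3 go wholly to train with a warning.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts = ("train", "validation", "test")
    assignment: dict[str, str] = {}
    by_stratum: dict[str, list[str]] = {}
    for pid in patient_ids:
        by_stratum.setdefault(strata[pid], []).append(pid)
    for label in sorted(by_stratum):
        members = sorted(by_stratum[label])
        rng.shuffle(members)
        n = len(members)
        if n < 3:
            warnings.warn(f"stratum {label!r} has {n} patient(s); allocated to train")
            for pid in members:
                assignment[pid] = "train"
            continue
        exact = [f * n for f in fractions]
        counts = [int(e) for e in exact]
        remainders = [e - c for e, c in zip(exact, counts)]
        while sum(counts) < n:
            i = int(np.argmax(remainders))
            counts[i] += 1
            remainders[i] = -1.0
        cursor = 0
        for part, c in zip(parts, counts):
            for pid in members[cursor:cursor + c]:
                assignment[pid] = part
            cursor += c
    return SplitAssignment(partition=assignment, strata=dict(strata))


def rank_features_gain(matrix: pd.DataFrame, target: Sequence[float],
                       n_keep: int = 10) -> list[str]:
    """Optional recursive-feature-elimination hook over a gradient-boosting
    backend.  Disabled by default throughout the pipeline (no supervised
    prediction target ships with this package); provided for users who bring
    their own target.
    """
    from sklearn.feature_selection import RFE  # lazy: optional extra
    from xgboost import XGBRegressor

    X = matrix.fillna(matrix.mean(numeric_only=True))
    model = XGBRegressor(n_estimators=50, max_depth=3, importance_type="gain",
                         random_state=0, verbosity=0)
    rfe = RFE(model, n_features_to_select=n_keep)
    rfe.fit(X.to_numpy(), np.asarray(target, dtype=float))
    return [c for c, keep in zip(matrix.columns, rfe.support_) if keep]
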