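"""Structured preprocessing and quality control for bladder diaries.

The pipeline applied to every raw diary before modeling:

1. **Imputation** — missing continuous fields (voided volume, intake volume)
   are replaced by that patient's mean over observed values of the same field;
   missing discrete fields (beverage type, urgency grade) by the patient-level
   mode (earliest-observed category wins ties).  A field missing for *all* of
   a patient's events is left missing and flagged unimputable.
2. **Anomaly detection** — per-patient, per-field IQR filtering (values
   outside [Q1 − k·IQR, Q3 + k·IQR]) plus time-series consistency checks
   (non-monotone timestamps, non-positive void intervals, physiologically
   implausible single volumes).  Anomalies are flagged, never deleted.
3. **Temporal alignment** — each void is paired with every intake in the
   preceding 60-minute window (closed boundary).
4. **Exclusion gate** — patients with <80% diary completion or >20% anomalous
   entries are excluded from modeling; both comparisons are strict, so a
   patient at exactly 80% completion and exactly 20% anomalies is retained.

Completion rate is defined as the fraction of expected daily record slots
present: each diary day expects (a) a void entry with volume, (b) an intake
entry, (c) a sleep record, (d) a training record — 4 slots/day.  Anomaly rate
is flagged events over total timestamped events, pooled across streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .diary import PatientDiary, day_partition

__all__ = [
    "QCReport",
    "AlignedPair",
    "ImputationSummary",
    "AnomalyReport",
    "impute_missing",
    "detect_anomalies",
    "align_intake_void",
    "qc_gate",
    "run_qc",
    "COMPLETION_THRESHOLD",
    "ANOMALY_THRESHOLD",
    "DEFAULT_IQR_K",
    "MAX_VOID_VOLUME_ML",
    "MAX_INTAKE_VOLUME_ML",
]

COMPLETION_THRESHOLD = 0.80
ANOMALY_THRESHOLD = 0.20
DEFAULT_IQR_K = 1.5
DEFAULT_ALIGNMENT_WINDOW_MIN = 60.0

# physiologic caps for single events (consistency check only, configurable)
MAX_VOID_VOLUME_ML = 1500.0
MAX_INTAKE_VOLUME_ML = 2000.0

# IQR rule needs at least this many observations of a field
_MIN_IQR_N = 4


@dataclass(frozen=True)
class QCReport:
    patient_id: str
    completion_rate: float
    anomaly_rate: float
    n_imputed_continuous: int
    n_imputed_discrete: int
    n_anomalies_flagged: int
    excluded: bool
    exclusion_reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        should_exclude = (self.completion_rate < COMPLETION_THRESHOLD
                          or self.anomaly_rate > ANOMALY_THRESHOLD)
        if self.excluded != should_exclude:
            raise ValueError("QCReport excluded flag inconsistent with rates")

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "completion_rate": self.completion_rate,
            "anomaly_rate": self.anomaly_rate,
            "n_imputed_continuous": self.n_imputed_continuous,
            "n_imputed_discrete": self.n_imputed_discrete,
            "n_anomalies_flagged": self.n_anomalies_flagged,
            "excluded": self.excluded,
            "exclusion_reasons": list(self.exclusion_reasons),
        }


@dataclass(frozen=True)
class AlignedPair:
    """An intake followed by a void within the alignment window."""

    intake_index: int
    void_index: int
    lag_minutes: float

    def __post_init__(self) -> None:
        if self.lag_minutes < 0:
            raise ValueError("lag must be non-negative")


@dataclass(frozen=True)
class ImputationSummary:
    n_imputed_continuous: int = 0
    n_imputed_discrete: int = 0
    unimputable_fields: tuple[str, ...] = ()


@dataclass(frozen=True)
class AnomalyFlag:
    stream: str  # "void" | "intake" | "leak"
    index: int
    reason: str  # "iqr:<field>" | "consistency:<rule>"


@dataclass(frozen=True)
class AnomalyReport:
    flags: tuple[AnomalyFlag, ...]
    n_events: int

    @property
    def n_flagged_events(self) -> int:
        # several reasons may hit the same event; count events once
        return len({(f.stream, f.index) for f in self.flags})

    @property
    def anomaly_rate(self) -> float:
        if self.n_events == 0:
            return 0.0
        return self.n_flagged_events / self.n_events


def _mode_earliest(values: Sequence) -> object:
    """Most frequent value; ties broken by earliest first occurrence."""
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best = None
    best_count = -1
    for v in values:  # stream order => earliest-first tie-break
        if counts[v] > best_count:
            best, best_count = v, counts[v]
    return best


def impute_missing(diary: PatientDiary) -> tuple[PatientDiary, ImputationSummary]:
    """Patient-level mean/mode imputation of missing event fields.

    Idempotent: a diary with no missing fields is returned unchanged.
    """
    n_cont = 0
    n_disc = 0
    unimputable: list[str] = []

    void_vols = [v.volume for v in diary.voids if v.volume is not None]
    void_vol_mean = float(np.mean(void_vols)) if void_vols else None
    grades = [v.urgency_grade for v in diary.voids if v.urgency_grade is not None]
    grade_mode = _mode_earliest(grades) if grades else None

    new_voids = []
    for v in diary.voids:
        upd = {}
        if v.volume is None:
            if void_vol_mean is not None:
                upd["volume"] = void_vol_mean
                n_cont += 1
        if v.urgency_grade is None and grade_mode is not None:
            upd["urgency_grade"] = grade_mode
            n_disc += 1
        new_voids.append(replace(v, **upd) if upd else v)
    if any(v.volume is None for v in new_voids):
        unimputable.append("void.volume")
    if any(v.urgency_grade is None for v in new_voids):
        unimputable.append("void.urgency_grade")

    intake_vols = [e.volume for e in diary.intakes if e.volume is not None]
    intake_vol_mean = float(np.mean(intake_vols)) if intake_vols else None
    beverages = [e.beverage_type for e in diary.intakes if e.beverage_type is not None]
    beverage_mode = _mode_earliest(beverages) if beverages else None

    new_intakes = []
    for e in diary.intakes:
        upd = {}
        if e.volume is None:
            if intake_vol_mean is not None:
                upd["volume"] = intake_vol_mean
                n_cont += 1
        if e.beverage_type is None and beverage_mode is not None:
            upd["beverage_type"] = beverage_mode
            n_disc += 1
        new_intakes.append(replace(e, **upd) if upd else e)
    if any(e.volume is None for e in new_intakes):
        unimputable.append("intake.volume")
    if any(e.beverage_type is None for e in new_intakes):
        unimputable.append("intake.beverage_type")

    out = replace(diary, voids=tuple(new_voids), intakes=tuple(new_intakes))
    return out, ImputationSummary(n_imputed_continuous=n_cont,
                                  n_imputed_discrete=n_disc,
                                  unimputable_fields=tuple(unimputable))


def _iqr_outlier_mask(values: np.ndarray, k: float) -> np.ndarray:
    """Boolean mask of values outside [Q1 − k·IQR, Q3 + k·IQR].

    Quartiles use linear interpolation (numpy default); the rule is skipped
    (all False) below the minimum sample size.
    """
    if values.size < _MIN_IQR_N:
        return np.zeros(values.shape, dtype=bool)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return (values < lo) | (values > hi)


def detect_anomalies(diary: PatientDiary, iqr_multiplier: float = DEFAULT_IQR_K,
                     max_void_volume: float = MAX_VOID_VOLUME_ML,
                     max_intake_volume: float = MAX_INTAKE_VOLUME_ML) -> AnomalyReport:
    """IQR filtering plus time-series consistency checks; flags, never deletes.

    Flags are monotone in the multiplier: every flag at k is also flagged at
    any smaller k (consistency flags do not depend on k at all).
    """
    if iqr_multiplier <= 0:
        raise ValueError("iqr_multiplier must be positive")
    flags: list[AnomalyFlag] = []

    # -- IQR per field ----------------------------------------------------
    vols = np.array([v.volume for v in diary.voids if v.volume is not None], dtype=float)
    vol_idx = [i for i, v in enumerate(diary.voids) if v.volume is not None]
    for i, out in zip(vol_idx, _iqr_outlier_mask(vols, iqr_multiplier)):
        if out:
            flags.append(AnomalyFlag("void", i, "iqr:volume"))

    ivols = np.array([e.volume for e in diary.intakes if e.volume is not None], dtype=float)
    ivol_idx = [i for i, e in enumerate(diary.intakes) if e.volume is not None]
    for i, out in zip(ivol_idx, _iqr_outlier_mask(ivols, iqr_multiplier)):
        if out:
            flags.append(AnomalyFlag("intake", i, "iqr:volume"))

    # void-to-void intervals (minutes); flag lands on the later void
    if len(diary.voids) >= 2:
        ts = [v.timestamp for v in diary.voids]
        gaps = np.array([(b - a).total_seconds() / 60.0 for a, b in zip(ts, ts[1:])])
        for j, out in zip(range(1, len(ts)), _iqr_outlier_mask(gaps, iqr_multiplier)):
            if out:
                flags.append(AnomalyFlag("void", j, "iqr:interval"))

    # -- consistency checks (independent of k) ----------------------------
    for stream, events in (("void", diary.voids), ("intake", diary.intakes),
                           ("leak", diary.leaks)):
        prev = None
        for i, e in enumerate(events):
            if prev is not None and e.timestamp <= prev:
                flags.append(AnomalyFlag(stream, i, "consistency:non_monotone_timestamp"))
            prev = e.timestamp
    for i, v in enumerate(diary.voids):
        if v.volume is not None and v.volume > max_void_volume:
            flags.append(AnomalyFlag("void", i, "consistency:volume_cap"))
        if v.volume is not None and v.volume < 0:
            flags.append(AnomalyFlag("void", i, "consistency:negative_volume"))
    for i, e in enumerate(diary.intakes):
        if e.volume is not None and e.volume > max_intake_volume:
            flags.append(AnomalyFlag("intake", i, "consistency:volume_cap"))

    return AnomalyReport(flags=tuple(flags), n_events=diary.n_events())


def align_intake_void(diary: PatientDiary,
                      window: float = DEFAULT_ALIGNMENT_WINDOW_MIN) -> list[AlignedPair]:
    """Pair each void with every intake in the preceding ``window`` minutes.

    The window is closed on both ends: an intake exactly ``window`` minutes
    before a void qualifies (lag == window).  Pair count is monotone
    non-decreasing in the window; window=0 yields only simultaneous pairs.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    pairs: list[AlignedPair] = []
    for vi, v in enumerate(diary.voids):
        for ii, e in enumerate(diary.intakes):
            lag = (v.timestamp - e.timestamp).total_seconds() / 60.0
            if 0.0 <= lag <= window:
                pairs.append(AlignedPair(intake_index=ii, void_index=vi, lag_minutes=lag))
    return pairs


def completion_rate(diary: PatientDiary) -> float:
    """Fraction of expected daily record slots present (4 slots per day:
    void-with-volume, intake, sleep record, training record)."""
    bundles = day_partition(diary)
    if not bundles:
        return 0.0
    n_days = diary.span_days
    present = 0
    by_date = {b.date: b for b in bundles}
    start = min(by_date)
    from datetime import timedelta
    for k in range(n_days):
        b = by_date.get(start + timedelta(days=k))
        if b is None:
            continue
        if any(v.volume is not None for v in b.voids):
            present += 1
        if b.intakes:
            present += 1
        if b.sleep:
            present += 1
        if b.training:
            present += 1
    return present / (4 * n_days)


def qc_gate(diary: PatientDiary, imputation: ImputationSummary,
            anomalies: AnomalyReport) -> QCReport:
    """Patient-level exclusion decision from completion and anomaly rates.

    Excluded iff completion < 80% or anomalies > 20% (strict inequalities:
    exactly 80%/20% is retained).  The decision depends on nothing else.
    """
    comp = completion_rate(diary)
    anom = anomalies.anomaly_rate
    reasons = []
    if comp < COMPLETION_THRESHOLD:
        reasons.append("completion")
    if anom > ANOMALY_THRESHOLD:
        reasons.append("anomalies")
    return QCReport(
        patient_id=diary.profile.patient_id,
        completion_rate=comp,
        anomaly_rate=anom,
        n_imputed_continuous=imputation.n_imputed_continuous,
        n_imputed_discrete=imputation.n_imputed_discrete,
        n_anomalies_flagged=anomalies.n_flagged_events,
        excluded=bool(reasons),
        exclusion_reasons=tuple(reasons),
    )


def run_qc(diary: PatientDiary, iqr_multiplier: float = DEFAULT_IQR_K,
           window: float = DEFAULT_ALIGNMENT_WINDOW_MIN
           ) -> tuple[PatientDiary, QCReport, AnomalyReport, list[AlignedPair]]:
    """Convenience chain: impute → detect anomalies → align → gate."""
    imputed, summary = impute_missing(diary)
    anomalies = detect_anomalies(imputed, iqr_multiplier=iqr_multiplier)
    pairs = align_intake_void(imputed, window=window)
    report = qc_gate(imputed, summary, anomalies)
    return imputed, report, anomalies, pairs
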