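"""Independent oracles used by the test suite.

Each oracle is a deliberately simple, straight-line recomputation kept
separate from the library code paths it checks:

* ``value_iteration`` — exact Q* for a small deterministic MDP.
* ``wilcoxon_exact_p`` — exhaustive sign-enumeration signed-rank p value.
* ``feature_oracle`` — loop-based recomputation of every feature slot.
"""

from __future__ import annotations

import itertools
from datetime import datetime, time, timedelta

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# value iteration on a deterministic MDP
# ---------------------------------------------------------------------------

def value_iteration(next_state: np.ndarray, rewards: np.ndarray,
                    gamma: float, tol: float = 1e-12,
                    max_iter: int = 100000) -> np.ndarray:
    """Exact Q* for a deterministic MDP given as (S, A) next-state ids and
    (S, A) immediate rewards."""
    q = np.zeros_like(rewards, dtype=float)
    for _ in range(max_iter):
        v_next = q.max(axis=1)[next_state]  # (S, A)
        q_new = rewards + gamma * v_next
        if np.abs(q_new - q).max() < tol:
            return q_new
        q = q_new
    raise RuntimeError("value iteration did not converge")


def random_deterministic_mdp(n_states: int, n_actions: int,
                             rng: np.random.Generator
                             ) -> tuple[np.ndarray, np.ndarray]:
    next_state = rng.integers(0, n_states, size=(n_states, n_actions))
    rewards = rng.uniform(-1.0, 1.0, size=(n_states, n_actions))
    return next_state, rewards


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank p by sign enumeration
# ---------------------------------------------------------------------------

def wilcoxon_exact_p(deltas) -> float:
    """Two-sided signed-rank p by exhaustive enumeration of all 2^n sign
    assignments (zeros dropped, mid-ranks for tied magnitudes):
    P(|W − μ| >= |W_obs − μ|) under the symmetric null."""
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / 2 ** n


# ---------------------------------------------------------------------------
# straight-line feature recomputation
# ---------------------------------------------------------------------------

_DAY_SHIFT = timedelta(hours=3)     # diary day boundary 03:00
_DAYTIME = (time(9, 0), time(21, 0))
_URGENT = 3


def _dday(ts: datetime, sleep_records=()):
    # diary day: 03:00 boundary, and an early-morning event still inside the
    # previous day's recorded sleep interval belongs to that previous day
    d = (ts - _DAY_SHIFT).date()
    prev = d - timedelta(days=1)
    for r in sleep_records:
        if r.date == prev and r.sleep_start <= ts < r.sleep_end:
            return prev
    return d


def _night_window(day, sleep_records):
    for r in sleep_records:
        if r.date == day:
            return r.sleep_start, r.sleep_end
    start = datetime.combine(day, time(21, 0))
    return start, datetime.combine(day + timedelta(days=1), time(9, 0))


def _is_night(ts, sleep_records):
    lo, hi = _night_window(_dday(ts, sleep_records), sleep_records)
    return lo <= ts < hi


def _mean(xs):
    xs = list(xs)
    return sum(xs) / len(xs) if xs else float("nan")


def feature_oracle(diary) -> dict[str, float]:
    """Recompute all 29 feature slots with plain loops."""
    nan = float("nan")
    out: dict[str, float] = {}
    p = diary.profile
    out["age"] = float(p.age)
    out["bmi"] = p.bmi if p.bmi is not None else nan
    out["qmax"] = p.qmax if p.qmax is not None else nan
    out["qave"] = p.qave if p.qave is not None else nan
    out["residual_urine"] = p.residual_urine if p.residual_urine is not None else nan

    all_days = set()
    for v in diary.voids:
        all_days.add(_dday(v.timestamp, diary.sleep))
    for e in diary.intakes:
        all_days.add(_dday(e.timestamp, diary.sleep))
    for e in diary.leaks:
        all_days.add(_dday(e.timestamp, diary.sleep))
    for a in diary.activity:
        all_days.add(_dday(a.interval_start, diary.sleep))
    for r in diary.sleep:
        all_days.add(r.date)
    for r in diary.training:
        all_days.add(r.date)
    for r in diary.assessments:
        all_days.add(r.date)
    span = (max(all_days) - min(all_days)).days + 1 if all_days else 0
    span = max(span, 1)

    out["daily_void_count"] = len(diary.voids) / span if diary.voids else nan

    # nocturia count/volume: mean per day over days holding any event
    noct_by_day = {d: [0, 0.0] for d in all_days}
    for v in diary.voids:
        if _is_night(v.timestamp, diary.sleep):
            d = _dday(v.timestamp, diary.sleep)
            noct_by_day[d][0] += 1
            noct_by_day[d][1] += v.volume or 0.0
    out["nocturia_count"] = _mean(c for c, _ in noct_by_day.values())
    out["nocturia_volume"] = _mean(vol for _, vol in noct_by_day.values())

    ts_sorted = sorted(v.timestamp for v in diary.voids)
    gaps = [(b - a).total_seconds() / 60 for a, b in zip(ts_sorted, ts_sorted[1:])]
    out["mean_voiding_interval"] = _mean(gaps)

    # daytime interval: within-09-21 same calendar day
    day_groups: dict = {}
    for v in diary.voids:
        if _DAYTIME[0] <= v.timestamp.time() < _DAYTIME[1]:
            day_groups.setdefault(v.timestamp.date(), []).append(v.timestamp)
    dg = []
    for ts in day_groups.values():
        ts.sort()
        dg += [(b - a).total_seconds() / 60 for a, b in zip(ts, ts[1:])]
    out["daytime_mean_voiding_interval"] = _mean(dg)

    # nocturnal polyuria: per-day ratio, averaged over defined days
    ratios = []
    for d in all_days:
        tot = noc = 0.0
        seen = False
        for v in diary.voids:
            if v.volume is None or _dday(v.timestamp, diary.sleep) != d:
                continue
            seen = True
            tot += v.volume
            if _is_night(v.timestamp, diary.sleep):
                noc += v.volume
        if seen and tot > 0:
            ratios.append(100.0 * noc / tot)
    out["nocturnal_polyuria_ratio"] = _mean(ratios)

    if diary.voids:
        end = max(v.timestamp for v in diary.voids)
        window = [v for v in diary.voids if v.timestamp > end - timedelta(days=7)]
        urgent = [v for v in window
                  if v.urgency_grade is not None and v.urgency_grade >= _URGENT]
        out["urgency_event_frequency"] = len(urgent) / len(window) if window else nan
    else:
        out["urgency_event_frequency"] = nan

    evr = []
    for v in diary.voids:
        if v.post_void_residual is None or v.volume is None:
            continue
        denom = v.volume + v.post_void_residual
        if denom > 0:
            evr.append(100.0 * v.volume / denom)
        elif v.post_void_residual == 0:
            evr.append(100.0)
    out["effective_voiding_rate"] = _mean(evr)

    def interval_for(days):
        groups: dict = {}
        for v in diary.voids:
            d = _dday(v.timestamp, diary.sleep)
            if d in days:
                groups.setdefault(d, []).append(v.timestamp)
        gs = []
        for ts in groups.values():
            ts.sort()
            gs += [(b - a).total_seconds() / 60 for a, b in zip(ts, ts[1:])]
        return _mean(gs)

    weekend = {d for d in all_days if d.weekday() >= 5}
    workday = {d for d in all_days if d.weekday() < 5}
    we, wo = interval_for(weekend), interval_for(workday)
    out["workday_weekend_interval_diff"] = (we - wo
                                            if we == we and wo == wo else nan)

    total = sum(e.volume for e in diary.intakes if e.volume is not None)
    irritant = sum(e.volume for e in diary.intakes
                   if e.volume is not None and e.beverage_type in ("coffee", "tea"))
    out["daily_intake_volume"] = total / span if diary.intakes else nan
    out["irritant_beverage_ratio"] = 100.0 * irritant / total if total > 0 else nan

    if diary.voids:
        paired = 0
        for v in diary.voids:
            for e in diary.intakes:
                lag = (v.timestamp - e.timestamp).total_seconds() / 60
                if 0 <= lag <= 60:
                    paired += 1
                    break
        out["fluid_void_association_index"] = paired / len(diary.voids)
    else:
        out["fluid_void_association_index"] = nan

    nai = []
    for r in diary.sleep:
        if r.night_arousals >= 1:
            cnt = sum(1 for v in diary.voids
                      if _dday(v.timestamp, diary.sleep) == r.date
                      and _is_night(v.timestamp, diary.sleep))
            nai.append(cnt / r.night_arousals)
    out["nocturia_arousal_index"] = _mean(nai)

    marker = 0.0
    ends = [a.interval_end for a in diary.activity if a.intensity == "vigorous"]
    for v in diary.voids:
        if v.urgency_grade is None or v.urgency_grade < _URGENT:
            continue
        for e in ends:
            lag = (v.timestamp - e).total_seconds() / 60
            if 0 <= lag <= 30:
                marker = 1.0
    out["postexercise_urgency_marker"] = marker

    for key, inst in (("oabss_score", "OABSS"), ("ipss_score", "IPSS"),
                      ("iciq_ui_sf_score", "ICIQ_UI_SF"),
                      ("sas_sds_score", "SAS_SDS"), ("psqi_score", "PSQI")):
        recs = sorted((a for a in diary.assessments if a.instrument == inst),
                      key=lambda a: a.date)
        out[key] = recs[-1].score if recs else nan

    presc = sum(1 for t in diary.training if t.prescribed)
    comp = sum(1 for t in diary.training if t.completed)
    out["completion_record_rate"] = comp / presc if presc else nan
    fb = [t.feedback_score for t in diary.training if t.feedback_score is not None]
    out["feedback_score_mean"] = _mean(fb)
    out["abnormal_event_count"] = float(sum(1 for t in diary.training if t.abnormal_event))
    out["usage_frequency"] = (len(diary.voids) + len(diary.intakes)
                              + len(diary.leaks) + len(diary.training)) / span

    # PFMT adherence decay
    pfmt = [t for t in diary.training if t.task == "pfmt"]
    days = sorted({t.date for t in diary.training})
    val = nan
    if pfmt and len(days) >= 10:
        first, last = days[0], days[-1]
        w1 = [t for t in pfmt if (t.date - first).days < 7]
        l3 = [t for t in pfmt if (last - t.date).days < 3]
        w1p = sum(1 for t in w1 if t.prescribed)
        l3p = sum(1 for t in l3 if t.prescribed)
        if w1p and l3p:
            w1r = sum(1 for t in w1 if t.completed) / w1p
            if w1r > 0:
                val = (sum(1 for t in l3 if t.completed) / l3p) / w1r
    out["pfmt_adherence_decay_rate"] = val
    return out
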