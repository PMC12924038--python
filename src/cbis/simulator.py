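"""Generative model of post-prostatectomy incontinence patient behavior.

The simulator plays the role of the study cohort: it emits
standards-conformant bladder diaries (for the QC and feature stages) and
responds to plan adjustments (for the decision engine), so the whole pipeline
is testable with no external data.  It is a test oracle with the qualitative
dynamics of behavioral rehabilitation — not a digital twin.

Generative structure
--------------------
Each patient carries a latent state: continence capacity (higher = fewer
leaks), bladder capacity, adherence propensity, a PFMT tolerability threshold
(minutes/day above which adherence erodes), circadian parameters (evening
intake share, irritant-beverage habit) and months post surgery.

* Daily void count: negative binomial around a latent mean (cohort default 8
  voids/day), modulated by fluid intake and bladder capacity.
* Leak episodes: Poisson; the log rate is linear in baseline incontinence
  severity (1 − continence) and decreases with the *lagged cumulative
  effective PFMT dose* (completed minutes, lagged by the response delay);
  a fully continent patient (capacity 1) never leaks.
* Nocturia: coupled to evening intake share and materialized inside the
  recorded sleep interval; night arousals >= nocturnal voids.
* Training records follow adherence propensity with slow natural decay;
  prescribing above the tolerability threshold accelerates the decay — the
  adherence/intensity trade-off the decision engine must navigate.
* ICIQ-like symptom score maps from current continence capacity.

A missingness + anomaly injector can corrupt diaries at configurable rates to
exercise preprocessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np

from .diary import (
    ActivityRecord,
    AssessmentRecord,
    IntakeEvent,
    LeakEvent,
    PatientDiary,
    PatientProfile,
    SleepRecord,
    TrainingRecord,
    VoidEvent,
)
from .rl import (
    ACTIONS,
    Action,
    MAINTAIN_ACTION_ID,
    QTable,
    RewardWeights,
    Transition,
    action_abruptness,
    INTERVAL_CHANGE_SPACING_DAYS,
    PFMT_CORRIDOR_MIN,
    PFMT_WEEKLY_CAP_MIN,
    _TIE_RANK,
    states_from_metric_arrays,
)

__all__ = [
    "LatentPatientState",
    "SimConfig",
    "generate_cohort",
    "generate_latents",
    "step_response",
    "rollout",
    "RolloutResult",
    "CohortPolicy",
    "RandomPolicy",
    "StaticPolicy",
    "GreedyPolicy",
    "train_policy",
]


@dataclass(frozen=True)
class LatentPatientState:
    """Unobserved patient characteristics driving diary generation."""

    continence_capacity: float      # [0, 1]; 1 = fully continent
    bladder_capacity: float         # mL
    adherence_propensity: float     # [0, 1]
    tolerability_threshold: float   # PFMT minutes/day tolerated
    evening_intake_fraction: float  # circadian: share of intake after 18:00
    irritant_habit: float           # habitual coffee+tea share of intake [0,1]
    months_post_surgery: float
    adherence_baseline: float | None = None  # recovery target; defaults to the
                                             # initial propensity
    pfmt_plan_minutes: float = 20.0
    interval_plan_minutes: float = 120.0
    dose_buffer: tuple[float, ...] = ()   # effective minutes awaiting the lag
    lagged_dose_hours: float = 0.0        # cumulative dose past the lag

    def __post_init__(self) -> None:
        for name, lo, hi in (("continence_capacity", 0, 1),
                             ("adherence_propensity", 0, 1),
                             ("evening_intake_fraction", 0, 1),
                             ("irritant_habit", 0, 1)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.bladder_capacity <= 0 or self.tolerability_threshold <= 0:
            raise ValueError("capacities must be positive")
        if self.adherence_baseline is None:
            object.__setattr__(self, "adherence_baseline", self.adherence_propensity)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the database-construction setting: 150 patients,
    3-day diaries, a cohort mean of 8 voids/day (>10,000 voiding events at
    full scale is reached with longer horizons).
    """

    n_patients: int = 150
    days: int = 3
    seed: int = 0
    # behavioral rates
    mean_voids_per_day: float = 8.0
    void_dispersion: float = 12.0          # negative-binomial shape (larger = tighter)
    intake_mean_ml: float = 1500.0
    intake_sd_ml: float = 200.0
    # leak model: log-rate = log(base) + severity*(1-c0) − effect*lagged dose
    leak_rate_base: float = 1.2            # episodes/day at full continence margin
    leak_severity_scale: float = 2.0
    evening_leak_scale: float = 0.8        # log-rate increase per unit evening
                                           # intake share above the 0.25 norm
    pfmt_leak_effect: float = 0.035        # per lagged cumulative effective hour
    response_lag_days: int = 7
    pfmt_gain_rate: float = 0.02           # continence gain per effective hour
    nocturia_base: float = 1.0             # episodes/night at mean evening intake
    # adherence dynamics
    natural_adherence_decay: float = 0.002  # per day
    tolerability_penalty: float = 0.005     # per day per 15 min above threshold
    motivation_gain: float = 0.01          # propensity gain per day per unit
                                            # relative leak-rate improvement
    adherence_recovery: float = 0.01        # daily relaxation of eroded propensity
                                            # back toward baseline once the plan
                                            # returns within tolerance
    noise_scale: float = 1.0                # 0 silences all behavioral noise
    # corruption injector
    missingness_rate: float = 0.0
    anomaly_rate: float = 0.0


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def generate_latents(config: SimConfig) -> list[LatentPatientState]:
    """Draw the latent cohort (deterministic in the config seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    latents = []
    for _ in range(config.n_patients):
        latents.append(LatentPatientState(
            continence_capacity=float(np.clip(rng.beta(2.5, 2.5), 0.02, 0.98)),
            bladder_capacity=float(np.clip(rng.normal(350, 60), 200, 600)),
            adherence_propensity=float(np.clip(rng.beta(5, 2), 0.05, 1.0)),
            tolerability_threshold=float(np.clip(rng.normal(45, 12), 20, 75)),
            evening_intake_fraction=float(np.clip(rng.beta(3, 7), 0.0, 1.0)),
            irritant_habit=float(np.clip(rng.beta(2, 6), 0.0, 1.0)),
            months_post_surgery=float(rng.uniform(1, 6)),
        ))
    return latents


def leak_rate(latent: LatentPatientState, config: SimConfig,
              lagged_dose_hours: float | None = None) -> float:
    """Daily leak-episode rate; exactly 0 for a fully continent patient."""
    c0 = latent.continence_capacity
    if c0 >= 1.0:
        return 0.0
    dose = (latent.lagged_dose_hours if lagged_dose_hours is None
            else lagged_dose_hours)
    return config.leak_rate_base * math.exp(
        config.leak_severity_scale * (1.0 - c0)
        + config.evening_leak_scale * (latent.evening_intake_fraction - 0.25)
        - config.pfmt_leak_effect * dose)


def _secs(ts: datetime) -> datetime:
    """Truncate to whole seconds (the delimited dialect's resolution)."""
    return ts.replace(microsecond=0)


def _unique_sorted_times(day: date, minutes: np.ndarray) -> list[datetime]:
    """Minute offsets from midnight -> strictly increasing datetimes (seconds
    nudged so the delimited dialect round-trips without dedup collisions)."""
    secs = np.sort((minutes * 60).astype(np.int64))
    for i in range(1, len(secs)):
        if secs[i] <= secs[i - 1]:
            secs[i] = secs[i - 1] + 1
    base = datetime.combine(day, time(0, 0))
    return [base + timedelta(seconds=int(s)) for s in secs]


def _generate_patient(pid: str, latent: LatentPatientState, config: SimConfig,
                      rng: np.random.Generator, start: date) -> PatientDiary:
    voids: list[VoidEvent] = []
    intakes: list[IntakeEvent] = []
    leaks: list[LeakEvent] = []
    sleep: list[SleepRecord] = []
    activity: list[ActivityRecord] = []
    training: list[TrainingRecord] = []
    noise = config.noise_scale

    profile = PatientProfile(
        patient_id=pid, sex="male",
        age=float(np.clip(rng.normal(67, 5), 45, 85)),
        bmi=float(np.clip(rng.normal(23.5, 3.0), 16, 40)),
        time_since_onset=latent.months_post_surgery * 30.0,
        qmax=float(np.clip(rng.normal(18, 4), 5, 40)),
        qave=float(np.clip(rng.normal(10, 2.5), 3, 25)),
        residual_urine=float(np.clip(rng.exponential(25), 0, 200)),
    )

    prop = latent.adherence_propensity
    adh = prop
    dose_hours = 0.0
    dose_buffer: list[float] = []  # fixed-delay buffer: dose matures after the lag
    beverage_types = ("water", "tea", "coffee", "functional_drink", "other")

    for d in range(config.days):
        day = start + timedelta(days=d)
        # ---- sleep -----------------------------------------------------
        sleep_start = _secs(datetime.combine(day, time(22, 0)) + timedelta(
            minutes=float(rng.normal(30, 20 * noise))))
        sleep_end = _secs(datetime.combine(day + timedelta(days=1), time(6, 0)) + timedelta(
            minutes=float(rng.normal(30, 20 * noise))))

        # ---- intake ----------------------------------------------------
        total_intake = max(400.0, rng.normal(config.intake_mean_ml,
                                             config.intake_sd_ml * noise))
        n_intakes = int(rng.integers(5, 9))
        evening = latent.evening_intake_fraction
        # intake times: waking hours, weighted toward the evening share
        t_int = np.where(rng.random(n_intakes) < evening,
                         rng.uniform(18 * 60, 22 * 60, n_intakes),
                         rng.uniform(7 * 60, 18 * 60, n_intakes))
        shares = rng.dirichlet(np.full(n_intakes, 4.0)) * total_intake
        p_irr = latent.irritant_habit
        bev_p = np.array([1 - p_irr - 0.08, p_irr * 0.55, p_irr * 0.45, 0.05, 0.03])
        bev_p = np.clip(bev_p, 0.0, None)
        bev_p /= bev_p.sum()
        kinds = rng.choice(5, size=n_intakes, p=bev_p)
        for ts, vol, k in zip(_unique_sorted_times(day, t_int), shares, kinds):
            intakes.append(IntakeEvent(timestamp=ts, volume=float(max(vol, 10.0)),
                                       beverage_type=beverage_types[k]))

        # ---- voids -----------------------------------------------------
        mu = (config.mean_voids_per_day
              * (total_intake / config.intake_mean_ml) ** 0.5
              * (350.0 / latent.bladder_capacity) ** 0.3)
        k_disp = config.void_dispersion
        n_voids = int(rng.negative_binomial(k_disp, k_disp / (k_disp + mu))) if noise > 0 \
            else int(round(mu))
        n_voids = max(n_voids, 2)
        noct_mu = config.nocturia_base * (0.5 + 1.5 * evening)
        n_noct = min(int(rng.poisson(noct_mu)) if noise > 0 else int(round(noct_mu)),
                     max(n_voids - 2, 0))
        n_day = n_voids - n_noct
        day_minutes = rng.uniform(6.8 * 60, 21.8 * 60, n_day)
        night_minutes = rng.uniform(23.0 * 60, 23.99 * 60, 0)  # placeholder
        # nocturnal voids inside the sleep interval
        sleep_span_min = (sleep_end - sleep_start).total_seconds() / 60.0
        noct_offsets = rng.uniform(10, sleep_span_min - 10, n_noct)
        noct_ts = [_secs(sleep_start + timedelta(minutes=float(m)))
                   for m in np.sort(noct_offsets)]
        daily_urine = 0.70 * total_intake
        vol_shares = rng.dirichlet(np.full(n_voids, 6.0)) * daily_urine
        urg_p = float(np.clip(0.12 + 0.5 * (1 - latent.continence_capacity)
                              + 0.3 * latent.irritant_habit, 0, 0.9))
        all_ts = _unique_sorted_times(day, day_minutes) + noct_ts
        for i, ts in enumerate(all_ts):
            grade = int(rng.integers(3, 6)) if rng.random() < urg_p else int(rng.integers(0, 3))
            pvr = float(rng.exponential(25)) if rng.random() < 0.4 else None
            symptoms = frozenset({"slow urine flow"}) if rng.random() < 0.1 else frozenset()
            voids.append(VoidEvent(
                timestamp=ts, volume=float(max(vol_shares[i], 20.0)),
                flow_rate=float(np.clip(rng.normal(12, 3), 2, 30)),
                urgency_grade=grade, symptoms=symptoms, post_void_residual=pvr))

        # ---- leaks -----------------------------------------------------
        lam = leak_rate(latent, config, lagged_dose_hours=dose_hours)
        n_leaks = int(rng.poisson(lam))
        for m in np.sort(rng.uniform(7 * 60, 22 * 60, n_leaks)):
            leaks.append(LeakEvent(
                timestamp=_secs(datetime.combine(day, time(0, 0))
                                + timedelta(minutes=float(m)))))

        # ---- activity --------------------------------------------------
        a_start = _secs(datetime.combine(day, time(16, 0)) + timedelta(
            minutes=float(rng.normal(0, 60 * noise))))
        intensity = "vigorous" if rng.random() < 0.2 else ("moderate" if rng.random() < 0.5 else "light")
        activity.append(ActivityRecord(
            interval_start=a_start, interval_end=a_start + timedelta(minutes=40),
            period="daytime", intensity=intensity,
            steps=int(np.clip(rng.normal(5500, 1500), 500, 20000))))

        # ---- training & adherence dynamics ------------------------------
        plan = latent.pfmt_plan_minutes
        completed_today = 0
        for task in ("pfmt", "bladder_training", "fluid_plan", "relaxation"):
            done = bool(rng.random() < adh) if noise > 0 else adh >= 0.5
            completed_today += done
            training.append(TrainingRecord(
                date=day, task=task, prescribed=True, completed=done,
                feedback_score=float(np.clip(rng.normal(7, 1.5), 0, 10)) if done else None,
                abnormal_event=bool(rng.random() < 0.01)))
        pfmt_done = training[-4].completed  # pfmt entry for today
        dose_buffer.append(plan * (1.0 if pfmt_done else 0.0))
        if len(dose_buffer) > config.response_lag_days:
            dose_hours += dose_buffer.pop(0) / 60.0
        # realized adherence drifts down naturally; prescribing above the
        # tolerability threshold erodes the underlying propensity
        rel_improve = 1.0 - math.exp(-config.pfmt_leak_effect * dose_hours)
        excess = max(plan - latent.tolerability_threshold, 0)
        recovery = (config.adherence_recovery * (latent.adherence_baseline - prop)
                    if excess == 0 else 0.0)
        prop = float(np.clip(
            prop - config.tolerability_penalty * excess / 15.0
            + config.motivation_gain * rel_improve + recovery, 0.0, 1.0))
        adh = prop * (1 - config.natural_adherence_decay) ** (d + 1)

        noct_for_sleep = len(noct_ts)
        sleep.append(SleepRecord(
            date=day, sleep_start=sleep_start, sleep_end=sleep_end,
            night_arousals=noct_for_sleep + int(rng.poisson(0.7))))

    # ---- assessments (first and last day) -------------------------------
    c_now = min(1.0, latent.continence_capacity
                + config.pfmt_gain_rate * dose_hours * (1 - latent.continence_capacity))
    assessments = [
        AssessmentRecord(date=start, instrument="ICIQ_UI_SF",
                         score=float(np.clip(round(21 * (1 - latent.continence_capacity)
                                                   + rng.normal(0, 1.0 * noise)), 0, 21))),
        AssessmentRecord(date=start, instrument="OABSS",
                         score=float(np.clip(round(rng.normal(6, 2)), 0, 15))),
        AssessmentRecord(date=start, instrument="IPSS",
                         score=float(np.clip(round(rng.normal(14, 5)), 0, 35))),
        AssessmentRecord(date=start, instrument="SAS_SDS",
                         score=float(np.clip(round(rng.normal(45, 8)), 20, 80))),
        AssessmentRecord(date=start, instrument="PSQI",
                         score=float(np.clip(round(rng.normal(8, 3)), 0, 21))),
    ]
    if config.days > 1:
        last = start + timedelta(days=config.days - 1)
        assessments.append(AssessmentRecord(
            date=last, instrument="ICIQ_UI_SF",
            score=float(np.clip(round(21 * (1 - c_now) + rng.normal(0, 1.0 * noise)), 0, 21))))

    diary = PatientDiary(profile=profile, voids=tuple(voids), intakes=tuple(intakes),
                         leaks=tuple(leaks), sleep=tuple(sleep),
                         activity=tuple(activity), training=tuple(training),
                         assessments=tuple(assessments))
    if config.missingness_rate > 0 or config.anomaly_rate > 0:
        diary = _corrupt(diary, config, rng)
    return diary


def _corrupt(diary: PatientDiary, config: SimConfig,
             rng: np.random.Generator) -> PatientDiary:
    """Missingness + anomaly injector (exercises the preprocessing stage)."""
    voids = list(diary.voids)
    for i, v in enumerate(voids):
        if rng.random() < config.missingness_rate:
            voids[i] = replace(v, volume=None)
        elif rng.random() < config.anomaly_rate:
            voids[i] = replace(v, volume=(v.volume or 200.0) * 8.0)
    intakes = list(diary.intakes)
    for i, e in enumerate(intakes):
        if rng.random() < config.missingness_rate:
            intakes[i] = replace(e, beverage_type=None)
    sleep = list(diary.sleep)
    if config.missingness_rate > 0:
        sleep = [r for r in sleep if rng.random() >= config.missingness_rate]
    return replace(diary, voids=tuple(voids), intakes=tuple(intakes),
                   sleep=tuple(sleep))


def generate_cohort(config: SimConfig = SimConfig(),
                    start: date = date(2024, 3, 4)) -> list[PatientDiary]:
    """Generate the synthetic cohort; fully determined by ``config.seed``.

    The default start date is a Monday so 3-day diaries are workday-only,
    matching a typical within-week collection window.
    """
    latents = generate_latents(config)
    rngs = _child_seeds(config.seed + 1, config.n_patients)
    return [
        _generate_patient(f"P{i:04d}", latent, config, rng, start)
        for i, (latent, rng) in enumerate(zip(latents, rngs))
    ]


def step_response(state: LatentPatientState, action: Action,
                  config: SimConfig = SimConfig(),
                  rng: np.random.Generator | None = None) -> LatentPatientState:
    """Advance one patient one day under a plan adjustment.

    The adjusted PFMT plan produces an effective dose (plan minutes times
    realized adherence); the dose enters a FIFO buffer and raises continence
    capacity only after the configured response lag.  A plan above the
    tolerability threshold erodes adherence propensity.  With
    ``noise_scale=0`` the step is deterministic (the maintain action on a
    zero plan leaves the state unchanged).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    noise = config.noise_scale
    plan = max(0.0, state.pfmt_plan_minutes + action.pfmt_delta)
    interval = max(30.0, state.interval_plan_minutes + action.void_interval_delta)
    evening = state.evening_intake_fraction
    if action.fluid_plan_adjust == "reduce_evening":
        evening = max(evening * 0.85, 0.05)
    elif action.fluid_plan_adjust == "redistribute":
        evening = evening + 0.15 * (0.25 - evening)

    if noise > 0:
        done = rng.random() < state.adherence_propensity
        dose_today = plan * (1.0 if done else 0.0)
    else:
        dose_today = plan * state.adherence_propensity  # expected dose

    buffer = state.dose_buffer + (dose_today,)
    lagged = state.lagged_dose_hours
    if len(buffer) > config.response_lag_days:
        lagged += buffer[0] / 60.0
        buffer = buffer[1:]
    if not any(buffer):  # all-zero buffer is canonically empty (same timing)
        buffer = ()

    matured = lagged - state.lagged_dose_hours
    c = min(1.0, state.continence_capacity
            + config.pfmt_gain_rate * matured * (1 - state.continence_capacity))

    # propensity is the underlying trait: eroded by prescribing above the
    # tolerability threshold, sustained by perceived symptom improvement
    # (natural decay acts on the *realized* adherence in the generators)
    rel_improve = 1.0 - math.exp(-config.pfmt_leak_effect * lagged)
    adh = state.adherence_propensity
    excess = max(plan - state.tolerability_threshold, 0)
    adh -= config.tolerability_penalty * excess / 15.0
    adh += config.motivation_gain * rel_improve
    if excess == 0:  # back within tolerance: eroded propensity recovers
        adh += config.adherence_recovery * (state.adherence_baseline - adh)
    if noise > 0:
        adh += float(rng.normal(0, 0.005 * noise))
    adh = float(np.clip(adh, 0.0, 1.0))

    return replace(state, continence_capacity=c, adherence_propensity=adh,
                   evening_intake_fraction=evening,
                   pfmt_plan_minutes=plan, interval_plan_minutes=interval,
                   dose_buffer=buffer, lagged_dose_hours=lagged)


# ---------------------------------------------------------------------------
# vectorized closed-loop rollout
# ---------------------------------------------------------------------------

_PFMT_DELTA = np.array([a.pfmt_delta for a in ACTIONS], dtype=float)
_INT_DELTA = np.array([a.void_interval_delta for a in ACTIONS], dtype=float)
_ABRUPT = np.array([action_abruptness(a) for a in ACTIONS], dtype=float)
_FLUID_ID = np.array([("reduce_evening", "none", "redistribute").index(a.fluid_plan_adjust)
                      for a in ACTIONS], dtype=np.int64)


class CohortPolicy:
    """Policy over the engine's state space, vectorized across a cohort."""

    def select(self, state_ids: np.ndarray, allowed: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class RandomPolicy(CohortPolicy):
    """Uniform draw over the admissible actions (behavior policy for offline
    data collection)."""

    def select(self, state_ids, allowed, rng):
        u = rng.random(allowed.shape)
        u = np.where(allowed, u, -1.0)
        return u.argmax(axis=1)


class StaticPolicy(CohortPolicy):
    """A fixed plan: always the maintain action."""

    def __init__(self, action_id: int = MAINTAIN_ACTION_ID):
        self.action_id = action_id

    def select(self, state_ids, allowed, rng):
        out = np.full(state_ids.shape, self.action_id, dtype=np.int64)
        ok = allowed[np.arange(len(out)), out]
        if not ok.all():  # fall back to any admissible action
            fallback = np.where(allowed, _TIE_RANK[None, :], np.inf).argmin(axis=1)
            out = np.where(ok, out, fallback)
        return out


class GreedyPolicy(CohortPolicy):
    """Epsilon-greedy over a fitted Q-table (ties -> least plan change)."""

    def __init__(self, qtable: QTable, epsilon: float = 0.0):
        self.q = qtable
        self.epsilon = epsilon

    def select(self, state_ids, allowed, rng):
        vals = self.q.values[state_ids]
        vals = np.where(allowed, vals, -np.inf)
        best = vals.max(axis=1, keepdims=True)
        cand = vals >= best - 1e-12
        greedy = np.where(cand, _TIE_RANK[None, :], np.inf).argmin(axis=1)
        if self.epsilon <= 0:
            return greedy
        explore = rng.random(len(greedy)) < self.epsilon
        nongreedy = allowed.copy()
        nongreedy[np.arange(len(greedy)), greedy] = False
        u = np.where(nongreedy, rng.random(allowed.shape), -1.0)
        alt = u.argmax(axis=1)
        has_alt = nongreedy.any(axis=1)
        return np.where(explore & has_alt, alt, greedy)


@dataclass
class RolloutResult:
    """Transition log (array form) plus per-patient outcome trajectories."""

    patient_ids: list[str]
    states: np.ndarray        # (n, horizon+1) state ids
    actions: np.ndarray       # (n, horizon) action ids
    rewards: np.ndarray       # (n, horizon)
    leaks: np.ndarray         # (n, horizon) daily leak episodes
    adherence: np.ndarray     # (n, horizon) realized adherence (A_t)
    engagement: np.ndarray    # (n, horizon) engagement (C_t)
    penalty: np.ndarray       # (n, horizon) penalty component (P_t)
    iciq: np.ndarray          # (n, horizon) symptom score trajectory
    dose: np.ndarray          # (n, horizon) lagged cumulative dose (hours)
    safety_violations: int    # emitted actions breaching a cap (should be 0)

    @property
    def horizon(self) -> int:
        return self.actions.shape[1]

    def cumulative_reward(self) -> np.ndarray:
        return self.rewards.sum(axis=1)

    def transition_rows(self) -> list[tuple[str, int, Transition]]:
        rows = []
        for i, pid in enumerate(self.patient_ids):
            for t in range(self.horizon):
                rows.append((pid, t, Transition(
                    int(self.states[i, t]), int(self.actions[i, t]),
                    float(self.rewards[i, t]), int(self.states[i, t + 1]))))
        return rows


def rollout(policy: CohortPolicy, cohort: Sequence[LatentPatientState],
            horizon: int, config: SimConfig = SimConfig(), seed: int = 0,
            weights: RewardWeights = RewardWeights()) -> RolloutResult:
    """Run a cohort under a policy for ``horizon`` daily decision points.

    The loop runs on daily behavioral aggregates (adherence, leak count, plan
    metrics) — the same latent dynamics as the diary generator, at the
    engine's decision cadence.  Cumulative safety caps (net PFMT change
    within ±30 min per 7 days; one voiding-interval change per 3 days) are
    enforced as an admissibility mask; emitted actions are audited against
    the caps post hoc.
    """
    n = len(cohort)
    rng = np.random.default_rng(seed)
    if horizon == 0:
        empty = np.zeros((n, 0))
        return RolloutResult(
            patient_ids=[f"P{i:04d}" for i in range(n)],
            states=np.zeros((n, 1), dtype=np.int64), actions=empty.astype(np.int64),
            rewards=empty, leaks=empty, adherence=empty, engagement=empty,
            penalty=empty, iciq=empty, dose=empty, safety_violations=0)

    noise = config.noise_scale
    c0 = np.array([p.continence_capacity for p in cohort])
    c = c0.copy()
    prop = np.array([p.adherence_propensity for p in cohort])
    prop0 = np.array([p.adherence_baseline for p in cohort])
    tol = np.array([p.tolerability_threshold for p in cohort])
    evening = np.array([p.evening_intake_fraction for p in cohort])
    irritant = np.array([p.irritant_habit for p in cohort]) * 100.0
    plan_pfmt = np.array([p.pfmt_plan_minutes for p in cohort])
    baseline_pfmt = plan_pfmt.copy()     # corridor anchor
    plan_int = np.array([p.interval_plan_minutes for p in cohort])
    drift = 1.0                          # (1 - natural decay)^t

    lag = config.response_lag_days
    buffer = np.zeros((n, lag))          # FIFO dose buffer (minutes)
    dose_hours = np.zeros(n)             # matured cumulative dose
    lam_baseline = np.where(c0 >= 1.0, 0.0,
                            config.leak_rate_base
                            * np.exp(config.leak_severity_scale * (1 - c0)
                                     + config.evening_leak_scale * (evening - 0.25)))
    roll7 = np.zeros((n, 7))             # last 7 days of pfmt deltas
    days_since_int = np.full(n, 999)

    states = np.zeros((n, horizon + 1), dtype=np.int64)
    actions = np.zeros((n, horizon), dtype=np.int64)
    rewards = np.zeros((n, horizon))
    leaks_out = np.zeros((n, horizon))
    adh_out = np.zeros((n, horizon))
    engage_out = np.zeros((n, horizon))
    pen_out = np.zeros((n, horizon))
    iciq_out = np.zeros((n, horizon))
    dose_out = np.zeros((n, horizon))
    violations = 0

    prev_leaks = np.full(n, np.inf)      # day 0: "improved" by convention
    prev_engage = np.full(n, np.inf)

    def observe(t: int) -> tuple[np.ndarray, ...]:
        a_real = np.clip(prop * drift + rng.normal(0, 0.05 * noise, n), 0, 1)
        lam = np.where(c0 >= 1.0, 0.0,
                       config.leak_rate_base
                       * np.exp(config.leak_severity_scale * (1 - c0)
                                + config.evening_leak_scale * (evening - 0.25)
                                - config.pfmt_leak_effect * dose_hours))
        lk = rng.poisson(lam).astype(float) if noise > 0 else lam
        interval_obs = plan_int + rng.normal(0, 8.0 * noise, n)
        iciq = np.clip(21 * (1 - c) + rng.normal(0, 1.0 * noise, n), 0, 21)
        irr = np.clip(irritant + rng.normal(0, 2.0 * noise, n), 0, 100)
        sid = states_from_metric_arrays(a_real, interval_obs, irr, iciq, lk)
        return sid, a_real, lk, iciq

    sid, a_real, lk, iciq = observe(0)
    states[:, 0] = sid

    for t in range(horizon):
        # admissibility from the cumulative safety caps
        roll_sum = roll7.sum(axis=1)
        pfmt_ok = np.abs(roll_sum[:, None] + _PFMT_DELTA[None, :]) <= PFMT_WEEKLY_CAP_MIN
        corridor_ok = np.abs(plan_pfmt[:, None] + _PFMT_DELTA[None, :]
                             - baseline_pfmt[:, None]) <= PFMT_CORRIDOR_MIN
        int_ok = (_INT_DELTA[None, :] == 0) | (days_since_int[:, None]
                                               >= INTERVAL_CHANGE_SPACING_DAYS)
        allowed = pfmt_ok & corridor_ok & int_ok

        aid = policy.select(states[:, t], allowed, rng)
        actions[:, t] = aid
        # post-hoc audit of the emitted actions against the caps
        dp = _PFMT_DELTA[aid]
        di = _INT_DELTA[aid]
        violations += int((np.abs(roll_sum + dp) > PFMT_WEEKLY_CAP_MIN).sum())
        violations += int((np.abs(plan_pfmt + dp - baseline_pfmt)
                           > PFMT_CORRIDOR_MIN).sum())
        violations += int(((di != 0) & (days_since_int
                                        < INTERVAL_CHANGE_SPACING_DAYS)).sum())

        approached = ((np.abs(roll_sum + dp) >= PFMT_WEEKLY_CAP_MIN - 5.0)
                      | (np.abs(plan_pfmt + dp - baseline_pfmt)
                         >= PFMT_CORRIDOR_MIN - 5.0)) & (dp != 0)
        approached |= (di != 0) & (days_since_int == INTERVAL_CHANGE_SPACING_DAYS)

        # apply the plan change
        plan_pfmt = np.maximum(plan_pfmt + dp, 0.0)
        plan_int = np.maximum(plan_int + di, 30.0)
        roll7 = np.roll(roll7, 1, axis=1)
        roll7[:, 0] = dp
        days_since_int = np.where(di != 0, 0, days_since_int + 1)

        # fluid-plan response: evening restriction shifts intake out of the
        # evening; redistribution moves the pattern toward the 0.25 norm
        fid = _FLUID_ID[aid]
        evening = np.where(fid == 0, np.maximum(evening * 0.85, 0.05), evening)
        evening = np.where(fid == 2, evening + 0.15 * (0.25 - evening), evening)

        # effective dose and lagged continence response
        done = (rng.random(n) < a_real) if noise > 0 else (a_real > 0)
        dose_today = plan_pfmt * np.where(done, 1.0, 0.0) * (a_real if noise == 0 else 1.0)
        matured = buffer[:, 0] / 60.0
        dose_hours += matured
        buffer = np.roll(buffer, -1, axis=1)
        buffer[:, -1] = dose_today
        c = np.minimum(1.0, c + config.pfmt_gain_rate * matured * (1 - c))

        # adherence dynamics: tolerability erosion of the propensity trait,
        # motivation feedback from perceived symptom improvement, and natural
        # decay of the realized adherence
        lam_now = np.where(c0 >= 1.0, 0.0,
                           config.leak_rate_base
                           * np.exp(config.leak_severity_scale * (1 - c0)
                                    + config.evening_leak_scale * (evening - 0.25)
                                    - config.pfmt_leak_effect * dose_hours))
        rel_improve = np.clip(1.0 - lam_now / np.maximum(lam_baseline, 1e-12), 0, 1)
        excess = np.maximum(plan_pfmt - tol, 0)
        prop = np.clip(prop - config.tolerability_penalty * excess / 15.0
                       + config.motivation_gain * rel_improve
                       + np.where(excess == 0,
                                  config.adherence_recovery * (prop0 - prop), 0.0)
                       + rng.normal(0, 0.005 * noise, n), 0, 1)
        drift *= 1 - config.natural_adherence_decay

        # reward components for this window
        engage = np.clip(prop * drift + rng.normal(0, 0.05 * noise, n), 0, 1)
        declined = engage < prev_engage - 0.02
        improved = lk <= prev_leaks
        pen = np.clip(approached.astype(float)
                      + 0.5 * (declined & ~improved), 0, 1)
        delta = _ABRUPT[aid]
        r = (weights.w_adherence * a_real + weights.w_engagement * engage
             - weights.w_abruptness * delta - weights.w_penalty * pen)
        rewards[:, t] = r
        leaks_out[:, t] = lk
        adh_out[:, t] = a_real
        engage_out[:, t] = engage
        pen_out[:, t] = pen
        iciq_out[:, t] = iciq
        dose_out[:, t] = dose_hours
        prev_leaks = lk
        prev_engage = engage

        sid, a_real, lk, iciq = observe(t + 1)
        states[:, t + 1] = sid

    return RolloutResult(
        patient_ids=[f"P{i:04d}" for i in range(n)],
        states=states, actions=actions, rewards=rewards, leaks=leaks_out,
        adherence=adh_out, engagement=engage_out, penalty=pen_out,
        iciq=iciq_out, dose=dose_out, safety_violations=violations)


def train_policy(cohort: Sequence[LatentPatientState], horizon: int,
                 config: SimConfig = SimConfig(), seed: int = 0,
                 n_initial_seeds: int = 10, n_iterations: int = 3,
                 n_recollect_seeds: int = 10, epsilon: float = 0.1,
                 alphas: tuple[float, ...] = (0.05, 0.05, 0.02),
                 gamma: float = 0.9, sweeps: int = 120,
                 tolerance: float = 1e-4) -> QTable:
    """Offline training recipe for the closed loop.

    Mirrors how a deployed system accumulates data: an initial batch of
    exploratory (uniform-random over admissible actions) behavior logs, then
    ``n_iterations`` rounds in which the current epsilon-greedy policy is
    redeployed, its logs appended, and the Q-table refit from scratch on the
    growing batch.  Later rounds use a smaller learning rate to polish the
    estimates.  Everything is deterministic in ``seed``.
    """
    from .rl import fit_offline  # local import avoids a cycle at module load

    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 30))
    transitions: list[Transition] = []
    for k in range(n_initial_seeds):
        res = rollout(RandomPolicy(), cohort, horizon, config=config,
                      seed=base + k)
        transitions.extend(t for _, _, t in res.transition_rows())
    fit = fit_offline(QTable(alpha=alphas[0], gamma=gamma), transitions,
                      sweeps=sweeps, tolerance=tolerance, seed=base)
    for it in range(n_iterations):
        for k in range(n_recollect_seeds):
            res = rollout(GreedyPolicy(fit.qtable, epsilon=epsilon), cohort,
                          horizon, config=config,
                          seed=base + 1000 * (it + 1) + k)
            transitions.extend(t for _, _, t in res.transition_rows())
        alpha = alphas[min(it + 1, len(alphas) - 1)]
        fit = fit_offline(QTable(alpha=alpha, gamma=gamma), transitions,
                          sweeps=sweeps, tolerance=tolerance, seed=base + it + 1)
    return fit.qtable
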