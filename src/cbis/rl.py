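"""Offline, safety-constrained tabular Q-learning for behavioral rehabilitation.

The decision layer observes a discretized multiday behavioral snapshot
(:class:`BehavioralState`: PFMT adherence, voiding-interval band, irritant
fluid ratio, ICIQ-UI SF band, recent leakage band — 3 bins each, 243 states)
and recommends a clinically admissible plan adjustment from a small discrete
action space (PFMT duration delta, voiding-interval prompt delta, fluid-plan
adjustment).  Action values are learned entirely from logged transitions with
batch Q-learning

    Q(s,a) <- Q(s,a) + alpha * (r + gamma * max_a' Q(s',a') - Q(s,a))

and recommendations use epsilon-greedy selection over the actions admitted by
a rule-based expert constraint layer, with a confidence gate routing
low-certainty recommendations to clinician review.  There is no function
approximation and no online exploration on patients.

The per-step reward is a bounded weighted composite

    r_t = w_A*A_t + w_C*C_t - w_D*Delta_t - w_P*P_t

of short-term adherence A_t, task completion/engagement C_t, abruptness of
the plan change Delta_t, and safety-threshold penalties P_t, each normalized
to [0, 1] before aggregation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .diary import PatientProfile
from .features import FeatureVector

__all__ = [
    "PFMT_DELTAS",
    "INTERVAL_DELTAS",
    "FLUID_ADJUSTS",
    "Action",
    "ACTIONS",
    "MAINTAIN_ACTION_ID",
    "action_abruptness",
    "BehavioralState",
    "N_STATES",
    "N_ACTIONS",
    "STATE_BINS",
    "encode_state",
    "state_from_metrics",
    "RewardComponents",
    "RewardWeights",
    "compute_reward",
    "Plan",
    "BehaviorWindow",
    "derive_components",
    "QTable",
    "Transition",
    "q_update",
    "FitResult",
    "fit_offline",
    "PolicyConfig",
    "ConstraintContext",
    "ConstraintRule",
    "RecentHistory",
    "default_safety_rules",
    "rule_from_dict",
    "load_rules",
    "evaluate_constraints",
    "AuditRecord",
    "ClinicianReviewRequired",
    "select_action",
    "confidence_gate",
    "greedy_action_table",
    "write_transition_log",
    "read_transition_log",
]

# ---------------------------------------------------------------------------
# action space
# ---------------------------------------------------------------------------

#: Admissible per-step PFMT duration changes (minutes/day).  +15 is the
#: "modest extension" step; +5 the reduced extension used when a larger step
#: is poorly tolerated.
PFMT_DELTAS = (-10, -5, 0, 5, 15)

#: Admissible voiding-interval prompt changes (minutes).
INTERVAL_DELTAS = (-15, 0, 15)

#: Fluid-plan adjustments.
FLUID_ADJUSTS = ("reduce_evening", "none", "redistribute")


@dataclass(frozen=True)
class Action:
    pfmt_delta: int
    void_interval_delta: int
    fluid_plan_adjust: str
    maintain: bool = False

    def __post_init__(self) -> None:
        if self.pfmt_delta not in PFMT_DELTAS:
            raise ValueError(f"pfmt_delta {self.pfmt_delta} outside safety range")
        if self.void_interval_delta not in INTERVAL_DELTAS:
            raise ValueError(f"void_interval_delta {self.void_interval_delta} outside safety range")
        if self.fluid_plan_adjust not in FLUID_ADJUSTS:
            raise ValueError(f"unknown fluid_plan_adjust {self.fluid_plan_adjust!r}")
        if self.maintain and (self.pfmt_delta or self.void_interval_delta
                              or self.fluid_plan_adjust != "none"):
            raise ValueError("maintain action must change nothing")


def _build_catalog() -> tuple[Action, ...]:
    actions = []
    for p, i, f in itertools.product(PFMT_DELTAS, INTERVAL_DELTAS, FLUID_ADJUSTS):
        actions.append(Action(p, i, f, maintain=(p == 0 and i == 0 and f == "none")))
    return tuple(actions)


#: Canonical action catalog; ids are indices into this tuple.
ACTIONS: tuple[Action, ...] = _build_catalog()
N_ACTIONS = len(ACTIONS)
MAINTAIN_ACTION_ID = next(i for i, a in enumerate(ACTIONS) if a.maintain)
_ACTION_INDEX: dict[Action, int] = {a: i for i, a in enumerate(ACTIONS)}


def action_id(action: Action) -> int:
    """Catalog id of an action (the maintain flag is derived, not identity)."""
    norm = Action(action.pfmt_delta, action.void_interval_delta,
                  action.fluid_plan_adjust,
                  maintain=(action.pfmt_delta == 0
                            and action.void_interval_delta == 0
                            and action.fluid_plan_adjust == "none"))
    return _ACTION_INDEX[norm]


def action_abruptness(action: Action) -> float:
    """Normalized magnitude of the plan change in [0, 1]: the larger of
    |pfmt delta|/15 and |interval delta|/15 (max-normalized pooling)."""
    return max(abs(action.pfmt_delta) / 15.0, abs(action.void_interval_delta) / 15.0)


# _TIE_RANK[a] = position of action a in (abruptness, canonical id) order;
# used to break equal-Q ties toward the least plan change.
_TIE_RANK = np.empty(N_ACTIONS, dtype=float)
for _rank, _idx in enumerate(sorted(range(N_ACTIONS),
                                    key=lambda i: (action_abruptness(ACTIONS[i]), i))):
    _TIE_RANK[_idx] = _rank
del _rank, _idx


# ---------------------------------------------------------------------------
# state space
# ---------------------------------------------------------------------------

#: Bin edges per state dimension.  A value exactly on a cut-point goes to the
#: upper bin.  3 bins per dimension -> 3^5 = 243 states.
STATE_BINS: dict[str, tuple[float, ...]] = {
    "adherence": (0.5, 0.8),          # fraction of prescribed tasks completed
    "interval": (90.0, 150.0),        # mean voiding interval, minutes
    "irritant_ratio": (10.0, 30.0),   # coffee+tea share of intake, percent
    "iciq": (8.0, 14.0),              # ICIQ-UI SF total score
    "leaks": (1.0, 4.0),              # leak episodes/day: 0 | 1-3 | >3
}

_DIM_ORDER = ("adherence", "interval", "irritant_ratio", "iciq", "leaks")
N_STATES = 3 ** len(_DIM_ORDER)


def _bin(value: float, edges: tuple[float, ...]) -> int:
    # upper-bin convention: value == edge -> the bin above the edge
    b = 0
    for e in edges:
        if value >= e:
            b += 1
    return b


@dataclass(frozen=True)
class BehavioralState:
    adherence_bin: int
    interval_bin: int
    irritant_bin: int
    iciq_bin: int
    leak_bin: int

    def __post_init__(self) -> None:
        for v in (self.adherence_bin, self.interval_bin, self.irritant_bin,
                  self.iciq_bin, self.leak_bin):
            if v not in (0, 1, 2):
                raise ValueError("state bins must be in {0, 1, 2}")

    @property
    def state_id(self) -> int:
        bins = (self.adherence_bin, self.interval_bin, self.irritant_bin,
                self.iciq_bin, self.leak_bin)
        sid = 0
        for b in bins:
            sid = sid * 3 + b
        return sid

    @classmethod
    def from_id(cls, sid: int) -> "BehavioralState":
        if not 0 <= sid < N_STATES:
            raise ValueError(f"state id {sid} outside 0..{N_STATES - 1}")
        bins = []
        for _ in range(5):
            bins.append(sid % 3)
            sid //= 3
        b = list(reversed(bins))
        return cls(*b)


def state_from_metrics(adherence: float, interval_min: float,
                       irritant_pct: float, iciq: float,
                       leaks_per_day: float) -> BehavioralState:
    """Deterministic binning of the five raw state metrics.

    An undefined (NaN) metric falls back to the middle bin with a warning —
    the neutral default when a dimension cannot be measured.
    """
    vals = {"adherence": adherence, "interval": interval_min,
            "irritant_ratio": irritant_pct, "iciq": iciq, "leaks": leaks_per_day}
    bins = {}
    for dim in _DIM_ORDER:
        v = vals[dim]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            warnings.warn(f"state dimension {dim!r} undefined; using middle bin")
            bins[dim] = 1
        else:
            bins[dim] = _bin(float(v), STATE_BINS[dim])
    return BehavioralState(bins["adherence"], bins["interval"],
                           bins["irritant_ratio"], bins["iciq"], bins["leaks"])


def encode_state(features: FeatureVector, leaks_per_day: float = float("nan"),
                 window_days: int = 3) -> BehavioralState:
    """Encode a feature vector (plus recent leak rate) into a state.

    The five state dimensions are PFMT adherence (completion record rate),
    mean voiding interval, irritant beverage ratio, latest ICIQ-UI SF score
    and recent leak episodes/day.
    """
    return state_from_metrics(
        adherence=features["completion_record_rate"],
        interval_min=features["mean_voiding_interval"],
        irritant_pct=features["irritant_beverage_ratio"],
        iciq=features["iciq_ui_sf_score"],
        leaks_per_day=leaks_per_day,
    )


def states_from_metric_arrays(adherence: np.ndarray, interval_min: np.ndarray,
                              irritant_pct: np.ndarray, iciq: np.ndarray,
                              leaks_per_day: np.ndarray) -> np.ndarray:
    """Vectorized state-id encoding (used by the cohort simulator)."""
    sid = np.zeros(np.shape(adherence), dtype=np.int64)
    for arr, dim in zip((adherence, interval_min, irritant_pct, iciq, leaks_per_day),
                        _DIM_ORDER):
        edges = STATE_BINS[dim]
        b = (np.asarray(arr)[..., None] >= np.asarray(edges)).sum(axis=-1)
        sid = sid * 3 + b
    return sid


# ---------------------------------------------------------------------------
# reward
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RewardComponents:
    adherence: float       # A_t
    engagement: float      # C_t
    abruptness: float      # Delta_t
    penalty: float         # P_t

    def __post_init__(self) -> None:
        for name in ("adherence", "engagement", "abruptness", "penalty"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"reward component {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class RewardWeights:
    """Composite-reward weights; defaults favor adherence and engagement over
    change-magnitude and safety penalties."""

    w_adherence: float = 0.4
    w_engagement: float = 0.3
    w_abruptness: float = 0.15
    w_penalty: float = 0.15

    def __post_init__(self) -> None:
        ws = (self.w_adherence, self.w_engagement, self.w_abruptness, self.w_penalty)
        if any(w < 0 for w in ws):
            raise ValueError("weights must be non-negative")
        if sum(ws) <= 0:
            raise ValueError("at least one weight must be positive")

    @property
    def reward_min(self) -> float:
        return -(self.w_abruptness + self.w_penalty)

    @property
    def reward_max(self) -> float:
        return self.w_adherence + self.w_engagement

    @property
    def span(self) -> float:
        return self.reward_max - self.reward_min


def compute_reward(components: RewardComponents,
                   weights: RewardWeights = RewardWeights()) -> float:
    """r_t = w_A*A + w_C*C − w_Δ*Δ − w_P*P, bounded by the analytic envelope."""
    r = (weights.w_adherence * components.adherence
         + weights.w_engagement * components.engagement
         - weights.w_abruptness * components.abruptness
         - weights.w_penalty * components.penalty)
    assert weights.reward_min - 1e-12 <= r <= weights.reward_max + 1e-12
    return float(r)


@dataclass(frozen=True)
class Plan:
    """A patient's current behavioral prescription."""

    pfmt_minutes: float              # daily PFMT duration
    void_interval_minutes: float     # target voiding interval
    fluid_plan: str = "none"

    def apply(self, action: Action) -> "Plan":
        return Plan(pfmt_minutes=max(0.0, self.pfmt_minutes + action.pfmt_delta),
                    void_interval_minutes=max(30.0, self.void_interval_minutes
                                              + action.void_interval_delta),
                    fluid_plan=action.fluid_plan_adjust)


@dataclass(frozen=True)
class BehaviorWindow:
    """Observed behavior between two consecutive decision points."""

    completed_tasks: int
    prescribed_tasks: int
    entries_logged: int
    entries_expected: int
    engagement_declined: bool = False
    leakage_improved: bool = True
    safety_threshold_approached: bool = False


#: Increment added to P_t when engagement declines while leakage fails to
#: improve (the poor-tolerability signal).
_P_DECLINE_INCREMENT = 0.5


def derive_components(prev_plan: Plan, new_plan: Plan,
                      behavior: BehaviorWindow) -> RewardComponents:
    """Reward components for one decision window.

    * A_t: completed/prescribed tasks (0 when nothing was prescribed).
    * C_t: diary entries logged over expected, clipped to [0, 1].
    * Delta_t: max-normalized plan-change magnitude.
    * P_t: 1 when a safety threshold was approached, plus an increment when
      engagement declined while leakage failed to improve; clipped to [0, 1].
    """
    a = (behavior.completed_tasks / behavior.prescribed_tasks
         if behavior.prescribed_tasks > 0 else 0.0)
    c = (behavior.entries_logged / behavior.entries_expected
         if behavior.entries_expected > 0 else 0.0)
    dpfmt = abs(new_plan.pfmt_minutes - prev_plan.pfmt_minutes)
    dint = abs(new_plan.void_interval_minutes - prev_plan.void_interval_minutes)
    delta = max(min(dpfmt / 15.0, 1.0), min(dint / 15.0, 1.0))
    p = 0.0
    if behavior.safety_threshold_approached:
        p += 1.0
    if behavior.engagement_declined and not behavior.leakage_improved:
        p += _P_DECLINE_INCREMENT
    return RewardComponents(adherence=min(max(a, 0.0), 1.0),
                            engagement=min(max(c, 0.0), 1.0),
                            abruptness=min(max(delta, 0.0), 1.0),
                            penalty=min(p, 1.0))


# ---------------------------------------------------------------------------
# Q-table and offline learning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transition:
    state_id: int
    action_id: int
    reward: float
    next_state_id: int


@dataclass
class QTable:
    """State-action value estimates with visit counts.

    ``values[s, a]`` is the expected cumulative discounted future reward of
    taking action a in state s; unvisited pairs carry ``initial_value``.
    """

    alpha: float = 0.1
    gamma: float = 0.9
    initial_value: float = 0.0
    n_states: int = N_STATES
    n_actions: int = N_ACTIONS
    values: np.ndarray = None  # type: ignore[assignment]
    visits: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must lie in [0, 1)")
        if self.values is None:
            self.values = np.full((self.n_states, self.n_actions),
                                  self.initial_value, dtype=float)
        if self.visits is None:
            self.visits = np.zeros((self.n_states, self.n_actions), dtype=np.int64)

    def copy(self) -> "QTable":
        return QTable(alpha=self.alpha, gamma=self.gamma,
                      initial_value=self.initial_value, n_states=self.n_states,
                      n_actions=self.n_actions, values=self.values.copy(),
                      visits=self.visits.copy())

    def _check(self, s: int, a: int) -> None:
        if not (0 <= s < self.n_states):
            raise KeyError(f"unknown state id {s}")
        if not (0 <= a < self.n_actions):
            raise KeyError(f"unknown action id {a}")

    def q(self, s: int, a: int) -> float:
        self._check(s, a)
        return float(self.values[s, a])

    def to_json_dict(self) -> dict:
        return {"alpha": self.alpha, "gamma": self.gamma,
                "initial_value": self.initial_value,
                "n_states": self.n_states, "n_actions": self.n_actions,
                "values": self.values.tolist(), "visits": self.visits.tolist()}

    @classmethod
    def from_json_dict(cls, doc: dict) -> "QTable":
        return cls(alpha=doc["alpha"], gamma=doc["gamma"],
                   initial_value=doc.get("initial_value", 0.0),
                   n_states=doc["n_states"], n_actions=doc["n_actions"],
                   values=np.asarray(doc["values"], dtype=float),
                   visits=np.asarray(doc["visits"], dtype=np.int64))


def q_update(q: QTable, transition: Transition) -> QTable:
    """One in-place application of the standard Q-learning update."""
    s, a, r, s2 = (transition.state_id, transition.action_id,
                   transition.reward, transition.next_state_id)
    q._check(s, a)
    q._check(s2, 0)
    td = r + q.gamma * float(q.values[s2].max()) - q.values[s, a]
    q.values[s, a] += q.alpha * td
    q.visits[s, a] += 1
    return q


@dataclass(frozen=True)
class FitResult:
    qtable: QTable
    converged: bool
    n_sweeps: int
    max_delta: float


def _sweep_python(values: np.ndarray, visits: np.ndarray, order: np.ndarray,
                  s: np.ndarray, a: np.ndarray, r: np.ndarray, s2: np.ndarray,
                  alpha: float, gamma: float) -> float:
    max_delta = 0.0
    for i in order:
        old = values[s[i], a[i]]
        new = old + alpha * (r[i] + gamma * values[s2[i]].max() - old)
        values[s[i], a[i]] = new
        visits[s[i], a[i]] += 1
        max_delta = max(max_delta, abs(new - old))
    return max_delta


try:  # optional acceleration; semantics identical to the python sweep
    from numba import njit as _njit

    @_njit(cache=False)
    def _sweep_numba(values, visits, order, s, a, r, s2, alpha, gamma):  # pragma: no cover
        max_delta = 0.0
        for k in range(order.shape[0]):
            i = order[k]
            best = values[s2[i], 0]
            for j in range(1, values.shape[1]):
                if values[s2[i], j] > best:
                    best = values[s2[i], j]
            old = values[s[i], a[i]]
            new = old + alpha * (r[i] + gamma * best - old)
            values[s[i], a[i]] = new
            visits[s[i], a[i]] += 1
            d = abs(new - old)
            if d > max_delta:
                max_delta = d
        return max_delta

    _SWEEP = _sweep_numba
except Exception:  # pragma: no cover
    _SWEEP = _sweep_python


def fit_offline(q: QTable, transitions: Sequence[Transition],
                sweeps: int = 500, tolerance: float = 1e-4,
                seed: int = 0) -> FitResult:
    """Batch Q-learning: repeated seeded-shuffled sweeps over a fixed
    transition log until the largest absolute Q change in a sweep falls below
    ``tolerance`` (or the sweep cap is reached)."""
    if not transitions:
        raise ValueError("transition batch is empty")
    q = q.copy()
    rng = np.random.default_rng(seed)
    order = np.arange(len(transitions), dtype=np.int64)
    s = np.array([t.state_id for t in transitions], dtype=np.int64)
    a = np.array([t.action_id for t in transitions], dtype=np.int64)
    r = np.array([t.reward for t in transitions], dtype=float)
    s2 = np.array([t.next_state_id for t in transitions], dtype=np.int64)
    if s.min() < 0 or s.max() >= q.n_states or s2.max() >= q.n_states:
        raise KeyError("transition references unknown state id")
    if a.min() < 0 or a.max() >= q.n_actions:
        raise KeyError("transition references unknown action id")
    max_delta = math.inf
    n_sweeps = 0
    for _ in range(sweeps):
        rng.shuffle(order)
        max_delta = float(_SWEEP(q.values, q.visits, order, s, a, r, s2,
                                 q.alpha, q.gamma))
        n_sweeps += 1
        if max_delta < tolerance:
            break
    return FitResult(qtable=q, converged=max_delta < tolerance,
                     n_sweeps=n_sweeps, max_delta=float(max_delta))


def greedy_action_table(q: QTable, allowed: np.ndarray | None = None) -> np.ndarray:
    """Greedy action id per state with the least-change tie-break.

    ``allowed``: optional boolean (n_states, n_actions) admissibility mask.
    """
    vals = q.values.copy()
    if allowed is not None:
        vals = np.where(allowed, vals, -np.inf)
    best = vals.max(axis=1, keepdims=True)
    cand = vals >= best - 1e-12
    ranks = np.where(cand, _TIE_RANK[None, :], np.inf)
    return ranks.argmin(axis=1)


# ---------------------------------------------------------------------------
# constraint layer, policy, confidence gate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolicyConfig:
    epsilon: float = 0.1
    seed: int = 0
    tie_break: str = "least_change"

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")


@dataclass(frozen=True)
class RecentHistory:
    """Rolling safety bookkeeping carried between decision points."""

    pfmt_change_7d: float = 0.0       # net PFMT change over the last 7 days
    days_since_interval_change: int = 999
    pfmt_plan: float = 20.0           # current prescribed PFMT minutes/day
    pfmt_baseline: float = 20.0       # baseline prescription (corridor anchor)


@dataclass(frozen=True)
class ConstraintContext:
    profile: PatientProfile | None
    state: BehavioralState
    action: Action
    history: RecentHistory


@dataclass(frozen=True)
class ConstraintRule:
    """Expert-authored admissibility rule.

    ``predicate(ctx)`` returns a verdict ("allow", "clip", "veto") or None
    when the rule does not apply; ``clip_to`` names the replacement action for
    clip verdicts.  Veto dominates clip dominates allow.
    """

    name: str
    predicate: Callable[[ConstraintContext], str | None]
    reason: str = ""
    clip_to: Action | None = None


_VERDICT_RANK = {"allow": 0, "clip": 1, "veto": 2}

_RULE_OPS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a is not None and a < b,
    "le": lambda a, b: a is not None and a <= b,
    "gt": lambda a, b: a is not None and a > b,
    "ge": lambda a, b: a is not None and a >= b,
    "in": lambda a, b: a in b,
    "abs_gt": lambda a, b: a is not None and abs(a) > b,
}


def _resolve(ctx: "ConstraintContext", dotted: str):
    obj: object = ctx
    for part in dotted.split("."):
        if obj is None:
            return None
        obj = getattr(obj, part)
    return obj


def rule_from_dict(doc: dict) -> "ConstraintRule":
    """Build a constraint rule from a declarative mapping.

    Schema::

        name: <str>
        verdict: allow | clip | veto
        reason: <str>
        when:  {"profile.age": {"ge": 75}, ...}     # context conditions
        match: {"action.pfmt_delta": {"gt": 5}}     # which actions it governs
        clip_to: {"pfmt_delta": 5, "void_interval_delta": 0,
                  "fluid_plan_adjust": "none"}      # for clip verdicts

    All ``when`` and ``match`` conditions must hold for the rule to fire;
    operators: eq, ne, lt, le, gt, ge, in, abs_gt.
    """
    verdict = doc.get("verdict", "veto")
    if verdict not in _VERDICT_RANK:
        raise ValueError(f"unknown verdict {verdict!r}")
    when = dict(doc.get("when", {}))
    match = dict(doc.get("match", {}))
    clip_to = None
    if doc.get("clip_to") is not None:
        c = doc["clip_to"]
        clip_to = Action(int(c.get("pfmt_delta", 0)),
                         int(c.get("void_interval_delta", 0)),
                         c.get("fluid_plan_adjust", "none"),
                         maintain=(not c.get("pfmt_delta")
                                   and not c.get("void_interval_delta")
                                   and c.get("fluid_plan_adjust", "none") == "none"))

    def predicate(ctx: "ConstraintContext") -> str | None:
        for dotted, ops in {**when, **match}.items():
            value = _resolve(ctx, dotted)
            for op, ref in ops.items():
                if op not in _RULE_OPS:
                    raise ValueError(f"unknown rule operator {op!r}")
                if not _RULE_OPS[op](value, ref):
                    return None
        return verdict

    return ConstraintRule(name=doc.get("name", "rule"), predicate=predicate,
                          reason=doc.get("reason", ""), clip_to=clip_to)


def load_rules(path) -> list["ConstraintRule"]:
    """Load a list of declarative rules from a YAML (or JSON) document."""
    import yaml

    docs = yaml.safe_load(open(path).read())
    if not isinstance(docs, list):
        raise ValueError("rules document must be a list of rule mappings")
    return [rule_from_dict(d) for d in docs]


#: Cumulative safety caps: the PFMT prescription stays within ±30 min of the
#: baseline prescription, with net change also rate-limited to ±30 min per
#: rolling 7 days; voiding-interval prompts at most one change per 3 days.
PFMT_WEEKLY_CAP_MIN = 30.0
PFMT_CORRIDOR_MIN = 30.0
INTERVAL_CHANGE_SPACING_DAYS = 3


def default_safety_rules() -> list[ConstraintRule]:
    def pfmt_rate_cap(ctx: ConstraintContext) -> str | None:
        if abs(ctx.history.pfmt_change_7d + ctx.action.pfmt_delta) > PFMT_WEEKLY_CAP_MIN:
            return "veto"
        return None

    def pfmt_corridor(ctx: ConstraintContext) -> str | None:
        new_plan = ctx.history.pfmt_plan + ctx.action.pfmt_delta
        if abs(new_plan - ctx.history.pfmt_baseline) > PFMT_CORRIDOR_MIN:
            return "veto"
        return None

    def interval_spacing(ctx: ConstraintContext) -> str | None:
        if (ctx.action.void_interval_delta != 0
                and ctx.history.days_since_interval_change < INTERVAL_CHANGE_SPACING_DAYS):
            return "veto"
        return None

    return [
        ConstraintRule("pfmt_weekly_cap", pfmt_rate_cap,
                       reason=f"net PFMT change would exceed ±{PFMT_WEEKLY_CAP_MIN:g} min/7d"),
        ConstraintRule("pfmt_corridor", pfmt_corridor,
                       reason=f"plan would leave ±{PFMT_CORRIDOR_MIN:g} min of the "
                              "baseline prescription"),
        ConstraintRule("interval_prompt_spacing", interval_spacing,
                       reason="voiding-interval prompts limited to one change per "
                              f"{INTERVAL_CHANGE_SPACING_DAYS} days"),
    ]


def evaluate_constraints(rules: Sequence[ConstraintRule],
                         profile: PatientProfile | None,
                         state: BehavioralState,
                         history: RecentHistory
                         ) -> tuple[dict[int, int], list[tuple[int, str, str]]]:
    """Evaluate every rule against every catalog action.

    Returns (admissible map {original id -> emitted id}, fired rules as
    (action id, rule name, verdict)).  A vetoed action is absent from the
    map; a clipped action maps to its replacement's id.
    """
    admissible: dict[int, int] = {}
    fired: list[tuple[int, str, str]] = []
    for aid, action in enumerate(ACTIONS):
        verdict = "allow"
        clip_target: Action | None = None
        for rule in rules:
            v = rule.predicate(ConstraintContext(profile, state, action, history))
            if v is None:
                continue
            fired.append((aid, rule.name, v))
            if _VERDICT_RANK[v] > _VERDICT_RANK[verdict]:
                verdict = v
                if v == "clip":
                    clip_target = rule.clip_to
        if verdict == "veto":
            continue
        if verdict == "clip" and clip_target is not None:
            admissible[aid] = action_id(clip_target)
        else:
            admissible[aid] = aid
    return admissible, fired


@dataclass(frozen=True)
class AuditRecord:
    """Accountability record attached to every recommendation."""

    state_id: int
    q_values: Mapping[int, float]         # over admissible actions
    rules_fired: tuple[tuple[int, str, str], ...]
    explored: bool
    chosen_action_id: int | None
    vetoed_action_ids: tuple[int, ...]


class ClinicianReviewRequired(Exception):
    """Raised when no admissible action exists; the case escalates to the
    clinician, no action is emitted."""

    def __init__(self, audit: AuditRecord):
        super().__init__("all actions vetoed by the constraint layer; clinician review required")
        self.audit = audit


def select_action(q: QTable, state: BehavioralState, policy: PolicyConfig,
                  constraints: Sequence[ConstraintRule] = (),
                  profile: PatientProfile | None = None,
                  history: RecentHistory = RecentHistory(),
                  rng: np.random.Generator | None = None
                  ) -> tuple[Action, AuditRecord]:
    """Epsilon-greedy selection over the constraint-admitted action set.

    With probability 1−ε the highest-Q admissible action is chosen (ties
    broken toward the least plan change, then canonical order); with
    probability ε a uniform draw over the remaining admissible actions is
    explored.  Vetoed actions are never emitted.
    """
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    sid = state.state_id
    admissible, fired = evaluate_constraints(constraints, profile, state, history)
    vetoed = tuple(aid for aid in range(N_ACTIONS) if aid not in admissible)
    qvals = {aid: q.q(sid, aid) for aid in admissible}
    if not admissible:
        raise ClinicianReviewRequired(AuditRecord(
            state_id=sid, q_values={}, rules_fired=tuple(fired), explored=False,
            chosen_action_id=None, vetoed_action_ids=vetoed))
    ids = sorted(admissible)
    greedy = min((aid for aid in ids
                  if qvals[aid] >= max(qvals.values()) - 1e-12),
                 key=lambda aid: (_TIE_RANK[aid], aid))
    explored = False
    chosen = greedy
    alternatives = [aid for aid in ids if aid != greedy]
    if alternatives and rng.random() < policy.epsilon:
        explored = True
        chosen = int(rng.choice(alternatives))
    emitted_id = admissible[chosen]
    audit = AuditRecord(state_id=sid, q_values=qvals, rules_fired=tuple(fired),
                        explored=explored, chosen_action_id=emitted_id,
                        vetoed_action_ids=vetoed)
    return ACTIONS[emitted_id], audit


def confidence_gate(q: QTable, state: BehavioralState, proposed: Action,
                    threshold: float = 0.3, n0: float = 5.0,
                    reward_span: float = 1.0,
                    admissible_ids: Iterable[int] | None = None) -> tuple[str, float]:
    """Route low-certainty recommendations to clinician review.

    Confidence = (Q-gap between best and second-best admissible action,
    normalized by the single-step reward span and clipped to [0, 1]) × the
    visit-count saturation n/(n+n0) of the proposed pair.  Below ``threshold``
    the verdict is "clinician_review", else "auto_approve".
    """
    sid = state.state_id
    ids = list(admissible_ids) if admissible_ids is not None else list(range(N_ACTIONS))
    vals = sorted((q.q(sid, aid) for aid in ids), reverse=True)
    gap = vals[0] - vals[1] if len(vals) >= 2 else reward_span
    gap_norm = min(max(gap / reward_span, 0.0), 1.0)
    n = float(q.visits[sid, action_id(proposed)])
    score = gap_norm * (n / (n + n0))
    verdict = "auto_approve" if score >= threshold else "clinician_review"
    return verdict, float(score)


# ---------------------------------------------------------------------------
# transition-log IO (delimited, versioned)
# ---------------------------------------------------------------------------

_LOG_HEADER = "patient_id\tt\tstate_id\taction_id\treward\tnext_state_id"
_LOG_MARKER = "# cbis-transitions v1"


def write_transition_log(path, rows: Iterable[tuple[str, int, Transition]]) -> None:
    """Rows are (patient_id, t, transition)."""
    with open(path, "w") as fh:
        fh.write(_LOG_MARKER + "\n" + _LOG_HEADER + "\n")
        for pid, t, tr in rows:
            fh.write(f"{pid}\t{t}\t{tr.state_id}\t{tr.action_id}"
                     f"\t{tr.reward:.10g}\t{tr.next_state_id}\n")


def read_transition_log(path) -> list[tuple[str, int, Transition]]:
    rows = []
    with open(path) as fh:
        marker = fh.readline().strip()
        if marker != _LOG_MARKER:
            raise ValueError(f"unrecognized transition log marker {marker!r}")
        header = fh.readline().strip()
        if header != _LOG_HEADER:
            raise ValueError("malformed transition log header")
        for line in fh:
            pid, t, s, a, r, s2 = line.rstrip("\n").split("\t")
            rows.append((pid, int(t), Transition(int(s), int(a), float(r), int(s2))))
    return rows
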