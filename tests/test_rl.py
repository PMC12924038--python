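"""State encoding, composite reward, offline Q-learning, constrained
epsilon-greedy selection, confidence gating."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cbis.rl import (
    ACTIONS,
    Action,
    AuditRecord,
    BehaviorWindow,
    BehavioralState,
    ClinicianReviewRequired,
    ConstraintRule,
    MAINTAIN_ACTION_ID,
    N_ACTIONS,
    N_STATES,
    Plan,
    PolicyConfig,
    QTable,
    RecentHistory,
    RewardComponents,
    RewardWeights,
    Transition,
    action_abruptness,
    action_id,
    compute_reward,
    confidence_gate,
    default_safety_rules,
    derive_components,
    fit_offline,
    q_update,
    select_action,
    state_from_metrics,
)

from _oracles import random_deterministic_mdp, value_iteration

MAINTAIN = ACTIONS[MAINTAIN_ACTION_ID]


class TestActionSpace:
    def test_catalog_is_full_cross_product(self):
        assert N_ACTIONS == 5 * 3 * 3
        assert len(set(ACTIONS)) == N_ACTIONS

    def test_out_of_range_deltas_refused(self):
        with pytest.raises(ValueError):
            Action(pfmt_delta=20, void_interval_delta=0, fluid_plan_adjust="none")
        with pytest.raises(ValueError):
            Action(pfmt_delta=0, void_interval_delta=30, fluid_plan_adjust="none")

    def test_maintain_flag_only_on_noop(self):
        assert MAINTAIN.pfmt_delta == 0 and MAINTAIN.void_interval_delta == 0
        assert sum(a.maintain for a in ACTIONS) == 1

    def test_abruptness_max_normalized(self):
        assert action_abruptness(Action(15, 0, "none")) == 1.0
        assert action_abruptness(Action(5, 0, "none")) == pytest.approx(1 / 3)
        assert action_abruptness(MAINTAIN) == 0.0


class TestStateEncoding:
    def test_known_snapshot_is_stable(self):
        s = state_from_metrics(adherence=0.95, interval_min=150.0,
                               irritant_pct=5.0, iciq=8.0, leaks_per_day=2.0)
        t = state_from_metrics(adherence=0.95, interval_min=150.0,
                               irritant_pct=5.0, iciq=8.0, leaks_per_day=2.0)
        assert s == t
        assert 0 <= s.state_id < N_STATES

    def test_boundary_goes_to_upper_bin(self):
        s = state_from_metrics(0.8, 90.0, 10.0, 8.0, 1.0)
        assert s.adherence_bin == 2      # 0.8 is the upper cut
        assert s.interval_bin == 1       # 90 enters the middle band
        assert s.irritant_bin == 1
        assert s.iciq_bin == 1           # 8 enters the 8-13 band
        assert s.leak_bin == 1

    def test_within_bin_variation_is_quantized_away(self):
        a = state_from_metrics(0.55, 100.0, 15.0, 10.0, 2.0)
        b = state_from_metrics(0.70, 140.0, 25.0, 12.0, 3.0)
        assert a == b

    def test_undefined_dimension_warns_and_uses_middle_bin(self):
        with pytest.warns(UserWarning, match="undefined"):
            s = state_from_metrics(float("nan"), 100.0, 15.0, 10.0, 2.0)
        assert s.adherence_bin == 1

    def test_state_id_roundtrip(self):
        for sid in (0, 1, 121, N_STATES - 1):
            assert BehavioralState.from_id(sid).state_id == sid


class TestReward:
    @pytest.mark.parametrize("a,c,d,p,expected", [
        (1, 1, 0, 0, 2.0), (0, 0, 1, 1, -2.0), (0.5, 0.5, 0.5, 0.5, 0.0)])
    def test_worked_examples_unit_weights(self, a, c, d, p, expected):
        w = RewardWeights(1, 1, 1, 1)
        r = compute_reward(RewardComponents(a, c, d, p), w)
        assert r == pytest.approx(expected)

    def test_component_out_of_range_refused(self):
        with pytest.raises(ValueError):
            RewardComponents(1.5, 0, 0, 0)

    def test_zero_weights_refused(self):
        with pytest.raises(ValueError):
            RewardWeights(0, 0, 0, 0)

    @given(a=st.floats(0, 1), c=st.floats(0, 1), d=st.floats(0, 1),
           p=st.floats(0, 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_reward_inside_analytic_envelope(self, a, c, d, p):
        w = RewardWeights()
        r = compute_reward(RewardComponents(a, c, d, p), w)
        assert w.reward_min - 1e-9 <= r <= w.reward_max + 1e-9


class TestDeriveComponents:
    BASE = Plan(pfmt_minutes=20, void_interval_minutes=120)

    def test_perfect_window_unchanged_plan(self):
        behavior = BehaviorWindow(completed_tasks=4, prescribed_tasks=4,
                                  entries_logged=12, entries_expected=12)
        c = derive_components(self.BASE, self.BASE, behavior)
        assert (c.adherence, c.engagement, c.abruptness, c.penalty) == (1, 1, 0, 0)

    def test_plus_15_is_maximal_abruptness(self):
        new = self.BASE.apply(Action(15, 0, "none"))
        c = derive_components(self.BASE, new,
                              BehaviorWindow(2, 4, 6, 12))
        assert c.abruptness == pytest.approx(1.0)

    def test_penalty_monotone_in_leak_outcome(self):
        behavior_bad = BehaviorWindow(1, 4, 3, 12, engagement_declined=True,
                                      leakage_improved=False)
        behavior_ok = BehaviorWindow(1, 4, 3, 12, engagement_declined=True,
                                     leakage_improved=True)
        p_bad = derive_components(self.BASE, self.BASE, behavior_bad).penalty
        p_ok = derive_components(self.BASE, self.BASE, behavior_ok).penalty
        assert p_bad > p_ok


class TestQUpdate:
    def test_standard_rule_single_step(self):
        q = QTable(alpha=0.5, gamma=0.9)
        q_update(q, Transition(0, 0, 1.0, 1))
        assert q.values[0, 0] == pytest.approx(0.5)  # 0 + 0.5*(1 + 0.9*0 - 0)
        assert q.visits[0, 0] == 1

    def test_alpha_zero_is_inert(self):
        q = QTable(alpha=0.0, gamma=0.9)
        q.values[:] = 2.0
        q_update(q, Transition(0, 0, 5.0, 1))
        assert q.values[0, 0] == pytest.approx(2.0)

    def test_full_overwrite_with_alpha_one_gamma_zero(self):
        q = QTable(alpha=1.0, gamma=0.0)
        q.values[0, 0] = 1.0
        q_update(q, Transition(0, 0, 0.0, 1))
        assert q.values[0, 0] == pytest.approx(0.0)

    def test_unknown_ids_rejected(self):
        q = QTable()
        with pytest.raises(KeyError):
            q_update(q, Transition(N_STATES, 0, 0.0, 0))
        with pytest.raises(KeyError):
            q_update(q, Transition(0, N_ACTIONS, 0.0, 0))


class TestFitOffline:
    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            fit_offline(QTable(), [])

    def test_single_repeated_transition_reaches_fixed_point(self):
        # Q(s,a) -> r + gamma * max Q(s') with s' having only this estimate 0
        q = QTable(alpha=0.5, gamma=0.9, n_states=2, n_actions=2)
        batch = [Transition(0, 0, 1.0, 1)] * 50
        res = fit_offline(q, batch, sweeps=200, tolerance=1e-10)
        assert res.qtable.values[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_huge_tolerance_one_converged_sweep(self):
        q = QTable(alpha=0.1, n_states=2, n_actions=2)
        res = fit_offline(q, [Transition(0, 0, 0.1, 1)], sweeps=50,
                          tolerance=1e6)
        assert res.converged and res.n_sweeps == 1

    def test_determinism(self):
        rng = np.random.default_rng(0)
        batch = [Transition(int(rng.integers(4)), int(rng.integers(3)),
                            float(rng.normal()), int(rng.integers(4)))
                 for _ in range(200)]
        a = fit_offline(QTable(n_states=4, n_actions=3), batch, seed=9)
        b = fit_offline(QTable(n_states=4, n_actions=3), batch, seed=9)
        assert np.array_equal(a.qtable.values, b.qtable.values)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_value_iteration_on_random_mdps(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_s = int(rng.integers(2, 7))
        n_a = int(rng.integers(2, 5))
        next_state, rewards = random_deterministic_mdp(n_s, n_a, rng)
        q_star = value_iteration(next_state, rewards, gamma=0.9)
        batch = [Transition(s, a, float(rewards[s, a]), int(next_state[s, a]))
                 for s in range(n_s) for a in range(n_a)]
        res = fit_offline(QTable(alpha=0.5, gamma=0.9, n_states=n_s,
                                 n_actions=n_a), batch,
                          sweeps=3000, tolerance=1e-9, seed=trial)
        assert np.abs(res.qtable.values - q_star).max() < 1e-3
        assert np.array_equal(res.qtable.values.argmax(axis=1),
                              q_star.argmax(axis=1))

    def test_reward_weight_monotonicity(self):
        """Raising the penalty weight weakly lowers the learned value of
        threshold-approaching actions on a fixed batch."""
        rng = np.random.default_rng(4)
        risky_action, safe_action = 1, 0
        batches = {}
        for w_p in (0.15, 0.6):
            w = RewardWeights(w_penalty=w_p)
            batch = []
            for _ in range(300):
                s = int(rng.integers(3))
                penalty = 1.0
                r_risky = compute_reward(RewardComponents(0.8, 0.8, 0.2, penalty), w)
                r_safe = compute_reward(RewardComponents(0.8, 0.8, 0.0, 0.0), w)
                batch.append(Transition(s, risky_action, r_risky, int(rng.integers(3))))
                batch.append(Transition(s, safe_action, r_safe, int(rng.integers(3))))
            batches[w_p] = fit_offline(QTable(alpha=0.1, n_states=3, n_actions=2),
                                       batch, sweeps=80, seed=0).qtable
        assert (batches[0.6].values[:, risky_action]
                <= batches[0.15].values[:, risky_action] + 1e-9).all()


class TestSelectAction:
    @staticmethod
    def _qtable_with_best(sid, best_aid, value=1.0):
        q = QTable()
        q.values[sid, best_aid] = value
        return q

    def test_epsilon_zero_is_greedy(self):
        state = BehavioralState.from_id(7)
        q = self._qtable_with_best(7, 31)
        action, audit = select_action(q, state, PolicyConfig(epsilon=0.0))
        assert action == ACTIONS[31]
        assert not audit.explored

    def test_tie_break_prefers_least_change(self):
        state = BehavioralState.from_id(3)
        q = QTable()  # all values equal -> maintain has minimal abruptness
        action, _ = select_action(q, state, PolicyConfig(epsilon=0.0))
        assert action.pfmt_delta == 0 and action.void_interval_delta == 0

    def test_epsilon_one_uniform_over_nongreedy(self):
        state = BehavioralState.from_id(11)
        q = self._qtable_with_best(11, MAINTAIN_ACTION_ID)
        rng = np.random.default_rng(2024)
        counts = np.zeros(N_ACTIONS)
        n_draws = 10_000
        for _ in range(n_draws):
            action, audit = select_action(q, state, PolicyConfig(epsilon=1.0),
                                          rng=rng)
            assert audit.explored
            counts[action_id(action)] += 1
        assert counts[MAINTAIN_ACTION_ID] == 0
        observed = counts[counts > 0]
        assert observed.size == N_ACTIONS - 1
        chi2, p = stats.chisquare(observed)
        assert p > 0.001  # consistent with the uniform sampling law

    def test_vetoed_greedy_falls_to_next_best(self):
        state = BehavioralState.from_id(5)
        q = QTable()
        q.values[5, 40] = 2.0
        q.values[5, MAINTAIN_ACTION_ID] = 1.0
        veto_40 = ConstraintRule(
            "no_big_steps",
            lambda ctx: "veto" if ctx.action == ACTIONS[40] else None,
            reason="test veto")
        action, audit = select_action(q, state, PolicyConfig(epsilon=0.0),
                                      constraints=[veto_40])
        assert action == MAINTAIN
        assert 40 in audit.vetoed_action_ids
        assert any(rule == "no_big_steps" for _, rule, _ in audit.rules_fired)

    def test_all_vetoed_escalates(self):
        state = BehavioralState.from_id(0)
        veto_all = ConstraintRule("block", lambda ctx: "veto", reason="all")
        with pytest.raises(ClinicianReviewRequired) as err:
            select_action(QTable(), state, PolicyConfig(), constraints=[veto_all])
        assert err.value.audit.chosen_action_id is None

    def test_pfmt_weekly_cap_vetoes_extension(self):
        state = BehavioralState.from_id(9)
        history = RecentHistory(pfmt_change_7d=25.0, pfmt_plan=45.0,
                                pfmt_baseline=20.0)
        q = QTable()
        q.values[9, :] = 0.0
        plus15 = action_id(Action(15, 0, "none"))
        q.values[9, plus15] = 5.0
        action, audit = select_action(q, state, PolicyConfig(epsilon=0.0),
                                      constraints=default_safety_rules(),
                                      history=history)
        assert plus15 in audit.vetoed_action_ids
        assert action.pfmt_delta + 25.0 <= 30.0

    def test_interval_prompt_spacing_vetoed(self):
        state = BehavioralState.from_id(9)
        history = RecentHistory(days_since_interval_change=1)
        q = QTable()
        shift = action_id(Action(0, 15, "none"))
        q.values[9, shift] = 5.0
        action, audit = select_action(q, state, PolicyConfig(epsilon=0.0),
                                      constraints=default_safety_rules(),
                                      history=history)
        assert action.void_interval_delta == 0
        assert shift in audit.vetoed_action_ids


class TestConfidenceGate:
    def test_unvisited_state_reviews(self):
        q = QTable()
        verdict, score = confidence_gate(q, BehavioralState.from_id(1), MAINTAIN)
        assert verdict == "clinician_review"
        assert score == 0.0

    def test_equal_values_review(self):
        q = QTable()
        q.visits[2, :] = 50
        verdict, _ = confidence_gate(q, BehavioralState.from_id(2), MAINTAIN)
        assert verdict == "clinician_review"

    def test_large_gap_many_visits_auto_approves(self):
        q = QTable()
        q.values[3, MAINTAIN_ACTION_ID] = 1.0
        q.visits[3, MAINTAIN_ACTION_ID] = 500
        verdict, score = confidence_gate(q, BehavioralState.from_id(3), MAINTAIN)
        assert verdict == "auto_approve"
        assert score > 0.3


class TestDeclarativeRules:
    def test_yaml_rule_clips_extension_for_elderly(self, tmp_path):
        from cbis.rl import load_rules
        from cbis.diary import PatientProfile

        rules_file = tmp_path / "rules.yaml"
        rules_file.write_text(
            "- name: elderly_small_steps\n"
            "  verdict: clip\n"
            "  reason: limit PFMT extension over age 75\n"
            "  when:\n"
            "    profile.age: {ge: 75}\n"
            "  match:\n"
            "    action.pfmt_delta: {gt: 5}\n"
            "  clip_to: {pfmt_delta: 5}\n")
        rules = load_rules(rules_file)
        assert len(rules) == 1

        state = BehavioralState.from_id(4)
        q = QTable()
        plus15 = action_id(Action(15, 0, "none"))
        q.values[4, plus15] = 3.0
        old = PatientProfile(patient_id="o", age=80.0)
        action, audit = select_action(q, state, PolicyConfig(epsilon=0.0),
                                      constraints=rules, profile=old)
        assert action.pfmt_delta == 5  # clipped, not vetoed
        young = PatientProfile(patient_id="y", age=60.0)
        action, _ = select_action(q, state, PolicyConfig(epsilon=0.0),
                                  constraints=rules, profile=young)
        assert action.pfmt_delta == 15  # rule does not fire

    def test_veto_rule_from_dict(self):
        from cbis.rl import rule_from_dict

        rule = rule_from_dict({"name": "no_interval_cuts", "verdict": "veto",
                               "match": {"action.void_interval_delta": {"lt": 0}}})
        state = BehavioralState.from_id(1)
        q = QTable()
        cut = action_id(Action(0, -15, "none"))
        q.values[1, cut] = 2.0
        action, audit = select_action(q, state, PolicyConfig(epsilon=0.0),
                                      constraints=[rule])
        assert action.void_interval_delta >= 0
        assert cut in audit.vetoed_action_ids

    def test_unknown_operator_rejected(self):
        from cbis.rl import rule_from_dict

        rule = rule_from_dict({"name": "bad", "verdict": "veto",
                               "match": {"action.pfmt_delta": {"wat": 1}}})
        with pytest.raises(ValueError, match="operator"):
            select_action(QTable(), BehavioralState.from_id(0),
                          PolicyConfig(), constraints=[rule])
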