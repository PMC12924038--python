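"""Fit a Q-table offline from simulated behavior logs and issue an audited,
safety-constrained recommendation.

The learner never explores on patients: it fits from logged transitions
(state, action, composite reward, next state) with batch Q-learning, then
recommendations come from epsilon-greedy selection over the actions admitted
by the expert constraint layer, with a confidence gate routing low-certainty
cases to clinician review.
"""

import numpy as np

from cbis.rl import (
    ACTIONS,
    PolicyConfig,
    RecentHistory,
    confidence_gate,
    default_safety_rules,
    select_action,
    BehavioralState,
)
from cbis.simulator import SimConfig, generate_latents, train_policy

config = SimConfig(n_patients=50, days=30, seed=9)
cohort = generate_latents(config)
qtable = train_policy(cohort, horizon=30, config=config, seed=9,
                      n_initial_seeds=3, n_iterations=1, n_recollect_seeds=3)

# a snapshot: good adherence, normal interval, low irritant intake,
# moderate symptoms, daily leaks
state = BehavioralState(adherence_bin=2, interval_bin=1, irritant_bin=0,
                        iciq_bin=1, leak_bin=1)
history = RecentHistory(pfmt_change_7d=0.0, days_since_interval_change=10,
                        pfmt_plan=20.0, pfmt_baseline=20.0)
action, audit = select_action(qtable, state, PolicyConfig(epsilon=0.0),
                              constraints=default_safety_rules(),
                              history=history)
verdict, score = confidence_gate(qtable, state, action)

print(f"state id {state.state_id} ({sum(qtable.visits[state.state_id])} visits in the log)")
print(f"recommended action: PFMT {action.pfmt_delta:+d} min, "
      f"interval {action.void_interval_delta:+d} min, "
      f"fluid plan: {action.fluid_plan_adjust}")
print(f"vetoed actions: {len(audit.vetoed_action_ids)} of {len(ACTIONS)}")
print(f"confidence: {score:.3f} -> {verdict}")
top = sorted(audit.q_values.items(), key=lambda kv: -kv[1])[:3]
print("top Q values:", [(aid, round(q, 3)) for aid, q in top])

# "clinician_review" means the Q-gap or the visit support is too thin to
# auto-approve; the case goes to the human reviewer with this audit record.
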