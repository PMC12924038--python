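# Methods

`cbis` re-implements, as an open and testable pipeline, the computational
core of a closed-loop behavioral rehabilitation system for post-prostatectomy
incontinence (PPI): bladder-diary quality control, behavioral feature
engineering, an offline safety-constrained Q-learning recommendation layer,
and the single-arm pre/post statistics used for pilot evaluation. Because no
patient data are deposited, a generative patient simulator supplies
standards-conformant diaries and closes the loop for end-to-end testing.

## Quality control

Raw diaries pass through a fixed pipeline:

1. **Imputation.** Missing continuous event fields (voided volume, intake
   volume) are replaced by the patient-level mean of observed values of the
   same field; missing discrete fields (beverage type, urgency grade) by the
   patient-level mode, ties broken toward the earliest observed category.
   A field missing for all of a patient's events stays missing and counts
   against completion. Imputation is idempotent.
2. **Anomaly flagging.** Per patient and per field, values outside
   [Q1 − k·IQR, Q3 + k·IQR] are flagged (k = 1.5 default; quartiles by
   linear interpolation, the numpy default; the rule is skipped below 4
   observations). Time-series consistency checks flag non-monotone
   timestamps, non-positive void intervals, and single events above
   physiologic caps (void > 1500 mL, intake > 2000 mL, configurable).
   Anomalies are flagged, never deleted; flags are monotone in k.
3. **Intake–void alignment.** Each void is paired with every intake in the
   preceding 60 minutes, closed on both boundaries (an intake exactly 60
   minutes earlier qualifies).
4. **Exclusion gate.** A patient is excluded iff diary completion < 80% or
   anomalous entries > 20%, both strict — exactly 80%/20% is retained.
   Neither rate has a published denominator, so both are declared here:
   completion is the fraction of expected daily record slots present (each
   diary day expects a void entry with volume, an intake entry, a sleep
   record, and a training record — 4 slots/day over the diary span);
   the anomaly rate is flagged events over all timestamped events, pooled
   across streams.

Diaries shorter than 3 days (the International Continence Society minimum
for reliable symptom capture) are refused by the modeling gate regardless of
QC rates.

## Feature engineering

The behavioral snapshot has 29 named slots in six categories (profile,
urinary behavior, drinking behavior, activity/sleep, validated scales,
system interaction); `docs/data_formats.md` tabulates all slots and units.
Two published construction methods are printed against each other's feature
names in the source table (the emptying-efficiency formula on the
nocturia–arousal row and vice versa); each formula is assigned here to its
clinically coherent feature: effective voiding rate =
volume/(volume + post-void residual)·100, nocturia–arousal index =
nocturnal voids / night arousals. A void counts as "with urgency" at
patient-scored grade ≥ 3 on the 0–5 scale (the cut is not published; 3 is
the scale midpoint at which urgency becomes clinically salient). Undefined
constructions (e.g. too few qualifying voids) carry NaN and propagate as
missing.

Collinear features (|Pearson r| > 0.9) are pruned greedily in canonical
slot order — the later slot of an offending pair is dropped; zero-variance
slots are dropped as degenerate. The 70/15/15 train/validation/test split is
stratified on leakage-severity bands (daily episodes 0, 1–2, 3–7, >7) ×
adherence tertiles, with seeded shuffling and largest-remainder allocation;
strata smaller than 3 go to train with a warning. A recursive-feature-
elimination hook over a gradient-boosting backend is provided but disabled
by default: no supervised prediction target ships with the package.

## Decision layer

**State.** Five clinician-interpretable dimensions, each cut into 3 bins
(boundary values go to the upper bin): PFMT adherence (<0.5, 0.5–0.8, ≥0.8),
mean voiding interval (<90, 90–150, ≥150 min), irritant beverage ratio
(<10, 10–30, ≥30 %), ICIQ-UI SF (0–7, 8–13, 14–21), recent leak episodes/day
(0, 1–3, >3) — 243 states, chosen for tabular tractability. An undefined
dimension falls to the middle bin with a warning.

**Actions.** The full cross product of PFMT duration deltas
{−10, −5, 0, +5, +15} min, voiding-interval prompt deltas {−15, 0, +15} min,
and fluid-plan adjustments {reduce_evening, none, redistribute} — 45
actions; the all-zero combination is the maintain action. The +15/+5 deltas
realize the worked clinical adjustments (modest extension; reduced extension
when poorly tolerated).

**Reward.** r_t = w_A·A_t + w_C·C_t − w_Δ·Δ_t − w_P·P_t with components in
[0, 1]: A_t = completed/prescribed tasks; C_t = diary entries logged over
expected, clipped; Δ_t = max(|ΔPFMT|/15, |Δinterval|/15) (max-normalized
pooling, so a +15 step scores 1); P_t = 1 when a safety threshold is
approached, plus 0.5 when engagement declines while leakage fails to
improve, clipped to [0, 1]. Default weights (0.4, 0.3, 0.15, 0.15) favor
adherence and engagement over change magnitude and penalties; the published
description fixes only the component roles, not the weights, so these are
declared package defaults (configurable).

**Learning.** Tabular Q-learning, strictly offline:
Q(s,a) ← Q(s,a) + α[r + γ·max_a′ Q(s′,a′) − Q(s,a)], fit by repeated
seeded-shuffled sweeps over a fixed transition batch until the largest
absolute change in a sweep falls below tolerance (defaults α = 0.1, γ = 0.9,
tolerance 1e-4, cap 500 sweeps; Q initialized at 0, optimistic
initialization available). An optional numba-jitted sweep kernel accelerates
fitting; its semantics are identical to the pure-python fallback. On
stochastic batches the fixed-α iteration reaches a noise floor rather than
the tolerance; the convergence status is reported, not assumed.

The closed-loop training recipe (`cbis.simulator.train_policy`) mirrors how
a deployed system accumulates data: an initial batch of exploratory logs
(uniform-random over admissible actions), then three rounds in which the
current ε-greedy (ε = 0.1) policy is redeployed on the simulator, its logs
appended, and the table refit (α = 0.05, then 0.02 for polishing). This
iterated batch scheme is what makes tabular estimates reliable enough for
greedy deployment; a single random batch leaves maximization bias in
rarely-visited state–action pairs.

**Safety and oversight.** A rule-based constraint layer is evaluated over
the whole catalog before selection; veto dominates clip dominates allow, and
vetoed actions are never emitted (all admissible actions exhausted →
escalation to clinician review, no action emitted). Default safety rules:
the PFMT prescription stays within ±30 min of the baseline prescription and
its net change is rate-limited to ±30 min per rolling 7 days (the published
cap wording is ambiguous between the two readings, so both are enforced);
voiding-interval prompts change at most once per 3 days. ε-greedy selection
(ε = 0.1 default) breaks exact Q ties toward the least plan change
(consonant with avoiding abrupt changes), then canonical order. The
confidence gate scores a recommendation as
(Q-gap between best and second-best admissible action, normalized by the
single-step reward span and clipped to [0, 1]) × n/(n + n₀) visit
saturation (n₀ = 5); below 0.3 the case routes to clinician review. Every
recommendation carries an audit record (Q values, rules fired, exploration
flag, confidence verdict).

Decisions are taken once per diary day; the cadence is a package choice (the
published description leaves it open).

## Patient simulator

The simulator is a test oracle expressing the qualitative dynamics of
behavioral rehabilitation, not a digital twin. Each patient has a latent
state: continence capacity c ∈ [0, 1], bladder capacity, adherence
propensity, a PFMT tolerability threshold (minutes/day), evening-intake
share, irritant-beverage habit, months post surgery.

* **Voids**: negative-binomial daily count around a latent mean (cohort
  default 8 voids/day), modulated by intake volume and bladder capacity;
  volumes split ~70% of intake by a Dirichlet; nocturnal voids are placed
  inside the recorded sleep interval, coupled to evening intake; night
  arousals ≥ nocturnal voids.
* **Leaks**: Poisson with log rate = log(base) + 2.0·(1 − c₀) +
  0.8·(evening share − 0.25) − 0.035·D, where D is the lagged cumulative
  effective PFMT dose in hours (completed minutes, maturing after a 7-day
  response lag). A fully continent patient never leaks. The dose coefficient
  and the continence gain rate (0.02/h, driving the ICIQ-like score
  21·(1 − c)) are calibrated so a typical adherent patient reproduces the
  reported pilot-scale 3-month improvements (≈40–60% fewer daily leak
  episodes; ≈5-point ICIQ reduction).
* **Adherence**: realized adherence = propensity × (1 − 0.002)^t (slow
  natural decay). The propensity trait erodes by 0.005/day per 15 min of
  prescription above the tolerability threshold (drawn N(45, 12), clipped to
  [20, 75] — most patients tolerate the +15 worked extension), recovers
  toward baseline at 1%/day once the plan returns within tolerance, and is
  sustained by perceived symptom improvement (+1%/day at full leak-rate
  resolution). Without the recovery and motivation terms the narrated
  trade-off — extend when tolerated, back off when completion declines —
  has no expression and plan maintenance is trivially optimal.
* **Fluid actions**: evening restriction multiplies the evening-intake share
  by 0.85 (floor 0.05); redistribution relaxes it toward the 0.25 norm.
  Voiding-interval prompts shift the interval plan only (no symptom channel
  is modeled for them).
* **Injector**: optional missingness and anomaly corruption (configurable
  rates) to exercise preprocessing.

Cohort generation materializes full event-level diaries (both file
dialects round-trip). The closed-loop rollout runs the same latent dynamics
at the daily-aggregate level, vectorized across patients — the decision
cadence is daily, so per-event detail never enters the RL loop; this keeps a
200-patient × 90-day × 100-seed policy comparison inside a few minutes of
CPU. Everything is deterministic in the run seed (per-patient generators are
spawned from a `SeedSequence`).

What passing simulator-based tests does **not** show: realism of event-level
microstructure (within-day void timing correlations, measurement error of
home uroflowmetry, reporting biases of self-kept diaries), nor clinical
efficacy of any policy — the simulator's dose–response is built in, so
closed-loop results validate the machinery, not the therapy.

## Pre/post pilot statistics

Outcomes are averaged over fixed 5-day baseline and final windows (shorter
windows are refused); binary daily symptoms become frequencies
(days present / 5 × 100). Per-variable change scores Δ = post − pre are
gated by Shapiro–Wilk at α = .05: normal → paired two-tailed t
(t = mean(Δ)/(sd/√n), df = n − 1, Cohen d = t/√n exactly, 95% CI
mean ± t·se); non-normal → Wilcoxon signed-rank with zeros dropped
(Wilcoxon's treatment), mid-ranks and tie-corrected variance, two-sided
normal-approximation z, effect size r = |z|/√(2n) with N = 2n paired
observations and n the original pair count — the convention that reproduces
the published nighttime-frequency effect size. A constant Δ sample routes
non-normal (W undefined). Spearman rank correlation explores associations
between change scores. No multiplicity adjustment (exploratory single-arm
design); reports carry that framing in a footer.

The normal approximation's accuracy at n ≤ 8 is bounded analytically: over
all tie-free sign configurations the largest |p_approx − p_exact| is 0.127
(at n = 5), so the test suite asserts agreement with the exhaustive
sign-enumeration oracle within 0.13. Heavily tied tiny samples (e.g. all
|Δ| equal) can deviate far more — a known breakdown of the approximation.

**Printed-table audit.** The pilot's raw data are unavailable, but its two
published summary tables contain derived cells recomputable from the other
printed cells. The audit checks mean difference = post − pre mean, CI
midpoint = mean difference, Cohen d = |t|/√16, median difference =
post − pre median, and r = |z|/√32, each to printed precision. 24 of 31
derived cells reproduce; 7 are flagged and reported unaltered: three Cohen d
cells that duplicate earlier rows of the same table, and four r cells one
printed unit away from |z|/√32 (0.99/0.99/0.95 printed vs 0.98/0.98/0.94
recomputed, and the dysuria row 0.61 vs 0.60).

## Numerical and degenerate-input choices

Quartiles by linear interpolation; alignment and post-exercise windows
closed on both boundaries; state-bin boundaries to the upper bin; mode ties
to the earliest observed; Q ties to the least plan change then canonical
order; division guards return NaN ("undefined") rather than raising
wherever the quantity is a feature, and raise wherever the caller violated a
contract (zero-variance t test, all-zero Wilcoxon, empty transition batch).
An all-zero dose buffer is canonically empty (identical maturation timing).

## Problem sizes used in the checks

The acceptance checks run at: 50 random MDPs (≤6 states, ≤4 actions) for the
value-iteration comparison; 100 random tie-free samples at n ≤ 8 for the
Wilcoxon bound; 200 patients × 90 days × 100 paired seeds for the
closed-loop policy comparison; 150-patient × 3-day cohorts for diary-level
statistics; 50 six-day diaries for the feature oracle; 200 patients ×
60 days for dose–response recovery by Poisson regression (with baseline
severity and evening share as covariates).

## Known limitations

* Tabular Q-learning cannot see the current PFMT plan (it is not a state
  dimension), so plan-dependent effects are learned only through their
  downstream behavioral signature; the safety corridor bounds the resulting
  drift.
* The confidence gate's Q-gap is structurally small whenever two admissible
  actions are near-equivalent (the fluid-plan dimension creates
  reward-identical variants), so conservative thresholds route many
  recommendations to review — intended behavior for a decision-support
  layer, but it limits autonomous operation.
* The exclusion-gate denominators, urgency cut, reward weights, state bins
  and decision cadence are declared package conventions where the published
  description is silent; all are configurable.
* The simulator omits wearable-device ingestion, within-day symptom
  dynamics, and any clinician-behavior model; its parameters are calibrated
  to reported aggregate effect sizes, not fit to patient data.
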