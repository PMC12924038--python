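# File formats

## Diary dialects

Both dialects carry a format version and round-trip losslessly through
`cbis.diary.read_diary` / `write_diary`.

### Long-form delimited log (`.csv`)

Line 1 is the version marker `# cbis-diary v1`; line 2 the CSV header; then
one event per row. `event_type` selects which value columns apply; all other
columns are left blank. Timestamps are ISO-8601 at second resolution,
timezone-naive local clock time.

| event_type | columns used |
|---|---|
| `profile` | `patient_id, sex, age, bmi, time_since_onset, qmax, qave, residual_urine` |
| `void` | `timestamp, volume, flow_rate, urgency_grade, symptoms` (`;`-separated), `post_void_residual` |
| `intake` | `timestamp, volume, beverage_type` (`water/tea/coffee/functional_drink/other`) |
| `leak` | `timestamp, count_weight` |
| `sleep` | `date, sleep_start, sleep_end, night_arousals` |
| `activity` | `interval_start, interval_end, period, intensity, steps` |
| `training` | `date, task` (`pfmt/bladder_training/fluid_plan/relaxation`), `prescribed, completed, feedback_score, abnormal_event` |
| `assessment` | `date, instrument` (`OABSS/IPSS/ICIQ_UI_SF/SAS_SDS/PSQI`), `score` |

Unparseable rows are collected into a reject report (line number + reason),
never silently dropped. Exact re-submissions — identical
(patient, timestamp, event kind) — are deduplicated, each recorded as a
reject with reason `duplicate`.

### Structured JSON (`.json`)

A single document mirroring the type structure:

```json
{"version": 1,
 "profile": {"patient_id": "...", "age": 66.0, ...},
 "voids": [{"timestamp": "...", "volume": 250.0, ...}],
 "intakes": [...], "leaks": [...], "sleep": [...],
 "activity": [...], "training": [...], "assessments": [...]}
```

## Day and night conventions

* Diary day boundary: 03:00 local. An event at 01:30 belongs to the previous
  diary day. An event after 03:00 that still falls inside the *previous*
  day's recorded sleep interval (e.g. a 05:30 nocturia episode) also belongs
  to the previous diary day.
* Night window: the patient's recorded sleep interval for that day; fallback
  21:00–09:00 when no sleep record covers the night. Daytime for the
  daytime-interval feature is 09:00–21:00.

## Feature schema (29 slots, canonical order)

| # | slot | category | units / range |
|---|---|---|---|
| 1 | `age` | basic | years |
| 2 | `bmi` | basic | kg/m² |
| 3 | `qmax` | basic | mL/s |
| 4 | `qave` | basic | mL/s |
| 5 | `residual_urine` | basic | mL |
| 6 | `daily_void_count` | urinary | voids/day |
| 7 | `nocturia_count` | urinary | episodes/night |
| 8 | `nocturia_volume` | urinary | mL/night |
| 9 | `mean_voiding_interval` | urinary | minutes |
| 10 | `daytime_mean_voiding_interval` | urinary | minutes (09–21 h gaps) |
| 11 | `nocturnal_polyuria_ratio` | urinary | % of 24-h volume |
| 12 | `urgency_event_frequency` | urinary | fraction (7-day window, grade ≥ 3) |
| 13 | `effective_voiding_rate` | urinary | % = volume/(volume+PVR)·100 |
| 14 | `workday_weekend_interval_diff` | urinary | minutes (weekend − workday) |
| 15 | `daily_intake_volume` | drinking | mL/day |
| 16 | `irritant_beverage_ratio` | drinking | % (coffee+tea of total) |
| 17 | `fluid_void_association_index` | drinking | fraction of voids ≤ 60 min post intake |
| 18 | `nocturia_arousal_index` | activity/sleep | nocturnal voids / night arousals |
| 19 | `postexercise_urgency_marker` | activity/sleep | binary (urgency ≤ 30 min after vigorous activity) |
| 20–24 | `oabss_score, ipss_score, iciq_ui_sf_score, sas_sds_score, psqi_score` | scales | instrument ranges |
| 25 | `completion_record_rate` | interaction | completed/prescribed tasks |
| 26 | `feedback_score_mean` | interaction | 0–10 |
| 27 | `abnormal_event_count` | interaction | count |
| 28 | `usage_frequency` | interaction | entries/day |
| 29 | `pfmt_adherence_decay_rate` | interaction | last-3-days rate / week-1 rate |

Collinearity pruning resolves ties by this order (the later slot is
dropped).

## Transition log

Tab-separated, versioned: marker line `# cbis-transitions v1`, header
`patient_id  t  state_id  action_id  reward  next_state_id`, one decision
point per row. State ids index the 243-state behavioral space
(`cbis.rl.BehavioralState.from_id`); action ids index the 45-action catalog
(`cbis.rl.ACTIONS`).
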