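"""Feature constructions, the 29-slot vector, pruning, stratified splitting."""

import math
from dataclasses import replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from cbis.diary import (
    ActivityRecord,
    IntakeEvent,
    PatientDiary,
    SleepRecord,
    TrainingRecord,
    VoidEvent,
)
from cbis.features import (
    FEATURE_NAMES,
    build_feature_vector,
    daytime_mean_voiding_interval,
    effective_voiding_rate,
    feature_matrix,
    fluid_void_association_index,
    irritant_beverage_ratio,
    nocturia_arousal_index,
    nocturnal_polyuria_ratio,
    pfmt_adherence_decay_rate,
    postexercise_urgency_marker,
    prune_collinear,
    stratified_split,
    urgency_event_frequency,
    workday_weekend_interval_diff,
)
from cbis.preprocessing import run_qc

from conftest import dt

D1 = date(2024, 3, 4)


def _diary(profile, **kw):
    return PatientDiary(profile=profile, **{k: tuple(v) for k, v in kw.items()})


class TestEngineeredFeatures:
    def test_daytime_interval_mean_of_gaps(self, profile):
        d = _diary(profile, voids=[VoidEvent(dt(1, 9)), VoidEvent(dt(1, 11)),
                                   VoidEvent(dt(1, 13))])
        assert daytime_mean_voiding_interval(d) == pytest.approx(120.0)

    def test_daytime_interval_zero_gap(self, profile):
        d = _diary(profile, voids=[VoidEvent(dt(1, 10)), VoidEvent(dt(1, 10))])
        assert daytime_mean_voiding_interval(d) == pytest.approx(0.0)

    def test_daytime_interval_undefined_without_in_window_pair(self, profile):
        d = _diary(profile, voids=[VoidEvent(dt(1, 8)), VoidEvent(dt(1, 22))])
        assert math.isnan(daytime_mean_voiding_interval(d))

    def test_polyuria_ratio_worked_example(self, profile):
        # night 600 mL, day 900 mL -> 40%
        d = _diary(profile, voids=[VoidEvent(dt(1, 23, 30), volume=600.0),
                                   VoidEvent(dt(1, 10), volume=500.0),
                                   VoidEvent(dt(1, 14), volume=400.0)])
        assert nocturnal_polyuria_ratio(d, D1) == pytest.approx(40.0)

    def test_polyuria_ratio_bounds(self, profile):
        day_only = _diary(profile, voids=[VoidEvent(dt(1, 10), volume=500.0)])
        assert nocturnal_polyuria_ratio(day_only, D1) == 0.0
        night_only = _diary(profile, voids=[VoidEvent(dt(1, 23), volume=500.0)])
        assert nocturnal_polyuria_ratio(night_only, D1) == 100.0

    def test_urgency_frequency_counts_grade_3_plus(self, profile):
        voids = [VoidEvent(dt(1, 8 + i), urgency_grade=(3 if i < 7 else 1))
                 for i in range(14)]
        d = _diary(profile, voids=voids)
        assert urgency_event_frequency(d) == pytest.approx(0.5)

    @pytest.mark.parametrize("grades,expected", [([0, 1, 2], 0.0),
                                                 ([3, 4, 5], 1.0)])
    def test_urgency_frequency_bounds(self, profile, grades, expected):
        d = _diary(profile, voids=[VoidEvent(dt(1, 8 + i), urgency_grade=g)
                                   for i, g in enumerate(grades)])
        assert urgency_event_frequency(d) == pytest.approx(expected)

    @pytest.mark.parametrize("volume,pvr,expected", [
        (300.0, 100.0, 75.0), (300.0, 0.0, 100.0), (0.0, 100.0, 0.0)])
    def test_effective_voiding_rate(self, profile, volume, pvr, expected):
        d = _diary(profile, voids=[VoidEvent(dt(1, 9), volume=volume,
                                             post_void_residual=pvr)])
        assert effective_voiding_rate(d) == pytest.approx(expected)

    @pytest.mark.parametrize("n_noct,arousals,expected", [
        (2, 4, 0.5), (0, 3, 0.0), (3, 3, 1.0)])
    def test_nocturia_arousal_index(self, profile, n_noct, arousals, expected):
        voids = [VoidEvent(dt(1, 23, 10 * i), volume=100.0) for i in range(n_noct)]
        d = _diary(profile, voids=voids,
                   sleep=[SleepRecord(date=D1, sleep_start=dt(1, 22),
                                      sleep_end=dt(2, 6), night_arousals=arousals)])
        assert nocturia_arousal_index(d, D1) == pytest.approx(expected)

    def test_nocturia_arousal_guard_zero_arousals(self, profile):
        d = _diary(profile, sleep=[SleepRecord(date=D1, sleep_start=dt(1, 22),
                                               sleep_end=dt(2, 6),
                                               night_arousals=0)])
        assert math.isnan(nocturia_arousal_index(d, D1))

    def test_irritant_ratio_worked_example(self, profile):
        d = _diary(profile, intakes=[
            IntakeEvent(dt(1, 8), 200.0, "coffee"),
            IntakeEvent(dt(1, 12), 100.0, "tea"),
            IntakeEvent(dt(1, 16), 700.0, "water")])
        assert irritant_beverage_ratio(d) == pytest.approx(30.0)

    @pytest.mark.parametrize("kind,expected", [("water", 0.0), ("coffee", 100.0)])
    def test_irritant_ratio_bounds(self, profile, kind, expected):
        d = _diary(profile, intakes=[IntakeEvent(dt(1, 8), 500.0, kind)])
        assert irritant_beverage_ratio(d) == pytest.approx(expected)

    def test_workday_weekend_difference(self, profile):
        # Mon gaps 120 min; Sat (2024-03-09) gaps 180 min -> +60
        voids = [VoidEvent(dt(1, 9)), VoidEvent(dt(1, 11)),
                 VoidEvent(dt(6, 9)), VoidEvent(dt(6, 12))]
        d = _diary(profile, voids=voids)
        assert workday_weekend_interval_diff(d) == pytest.approx(60.0)

    def test_workday_weekend_undefined_for_weekdays_only(self, tiny_diary):
        assert math.isnan(workday_weekend_interval_diff(tiny_diary))

    @pytest.mark.parametrize("minute,expected", [(20, 1.0), (45, 0.0)])
    def test_postexercise_urgency_window(self, profile, minute, expected):
        d = _diary(profile,
                   voids=[VoidEvent(dt(1, 10, minute), urgency_grade=4)],
                   activity=[ActivityRecord(interval_start=dt(1, 9, 30),
                                            interval_end=dt(1, 10, 0),
                                            intensity="vigorous")])
        assert postexercise_urgency_marker(d) == expected

    def test_postexercise_zero_without_vigorous_activity(self, profile):
        d = _diary(profile, voids=[VoidEvent(dt(1, 10), urgency_grade=5)])
        assert postexercise_urgency_marker(d) == 0.0

    def test_fluid_void_association_count_ratio(self, profile):
        voids = [VoidEvent(dt(1, 8 + i)) for i in range(8)]
        intakes = [IntakeEvent(dt(1, 7, 30), 200.0, "water"),
                   IntakeEvent(dt(1, 8, 30), 200.0, "water")]
        # voids at 08:00 and 09:00 have an intake within the prior hour
        d = _diary(profile, voids=voids, intakes=intakes)
        assert fluid_void_association_index(d) == pytest.approx(0.25)

    def test_fluid_void_association_bounds(self, profile):
        no_intake = _diary(profile, voids=[VoidEvent(dt(1, 9))])
        assert fluid_void_association_index(no_intake) == 0.0
        paired = _diary(profile, voids=[VoidEvent(dt(1, 9))],
                        intakes=[IntakeEvent(dt(1, 8, 30), 100.0, "water")])
        assert fluid_void_association_index(paired) == 1.0

    def test_adherence_decay_worked_example(self, profile):
        # two PFMT sessions/day: week 1 completes 14/14, the last 3 days
        # complete 3/6 -> decay ratio (3/6)/(14/14) = 0.5
        training = []
        for i in range(14):
            day = D1 + timedelta(days=i)
            for k in range(2):
                done = i < 7 or (i >= 11 and k == 0)
                training.append(TrainingRecord(date=day, task="pfmt",
                                               prescribed=True, completed=done))
        d = _diary(profile, training=training)
        assert pfmt_adherence_decay_rate(d) == pytest.approx(0.5)

    def test_adherence_decay_constant_perfect(self, profile):
        training = [TrainingRecord(date=D1 + timedelta(days=i), task="pfmt",
                                   prescribed=True, completed=True)
                    for i in range(12)]
        d = _diary(profile, training=training)
        assert pfmt_adherence_decay_rate(d) == pytest.approx(1.0)

    def test_adherence_decay_guards(self, profile):
        short = _diary(profile, training=[
            TrainingRecord(date=D1 + timedelta(days=i), task="pfmt",
                           prescribed=True, completed=True) for i in range(5)])
        assert math.isnan(pfmt_adherence_decay_rate(short))
        zero_week1 = _diary(profile, training=[
            TrainingRecord(date=D1 + timedelta(days=i), task="pfmt",
                           prescribed=True, completed=(i >= 7))
            for i in range(12)])
        assert math.isnan(pfmt_adherence_decay_rate(zero_week1))


class TestFeatureVector:
    def test_census_is_29_in_schema_order(self, tiny_diary):
        _, report, _, _ = run_qc(tiny_diary)
        fv = build_feature_vector(tiny_diary, report)
        assert tuple(fv.values.keys()) == FEATURE_NAMES
        assert len(fv.values) == 29

    def test_excluded_patient_refused(self, profile):
        d = _diary(profile, voids=[VoidEvent(dt(1, 9), 200.0),
                                   VoidEvent(dt(3, 9), 200.0)])
        _, report, _, _ = run_qc(d)
        assert report.excluded
        with pytest.raises(ValueError, match="excluded"):
            build_feature_vector(d, report)

    def test_deterministic(self, tiny_diary):
        _, report, _, _ = run_qc(tiny_diary)
        a = build_feature_vector(tiny_diary, report)
        b = build_feature_vector(tiny_diary, report)
        assert a.values == b.values

    def test_empty_optional_streams_leave_other_slots_intact(self, tiny_diary):
        _, report, _, _ = run_qc(tiny_diary)
        full = build_feature_vector(tiny_diary, report)
        stripped = replace(tiny_diary, assessments=(), activity=())
        fv = build_feature_vector(stripped, report)
        assert math.isnan(fv["iciq_ui_sf_score"])
        assert fv["postexercise_urgency_marker"] == 0.0
        assert fv["daily_void_count"] == full["daily_void_count"]

    def test_time_translation_invariance(self, tiny_diary):
        """Shifting every event by a whole week changes nothing."""
        _, report, _, _ = run_qc(tiny_diary)
        week = timedelta(days=7)
        shifted = PatientDiary(
            profile=tiny_diary.profile,
            voids=tuple(replace(v, timestamp=v.timestamp + week)
                        for v in tiny_diary.voids),
            intakes=tuple(replace(e, timestamp=e.timestamp + week)
                          for e in tiny_diary.intakes),
            leaks=tuple(replace(e, timestamp=e.timestamp + week)
                        for e in tiny_diary.leaks),
            sleep=tuple(replace(r, date=r.date + week,
                                sleep_start=r.sleep_start + week,
                                sleep_end=r.sleep_end + week)
                        for r in tiny_diary.sleep),
            activity=tuple(replace(a, interval_start=a.interval_start + week,
                                   interval_end=a.interval_end + week)
                           for a in tiny_diary.activity),
            training=tuple(replace(t, date=t.date + week)
                           for t in tiny_diary.training),
            assessments=tuple(replace(s, date=s.date + week)
                              for s in tiny_diary.assessments))
        base = build_feature_vector(tiny_diary, report)
        moved = build_feature_vector(shifted, report)
        for name in FEATURE_NAMES:
            b, m = base[name], moved[name]
            assert (math.isnan(b) and math.isnan(m)) or b == pytest.approx(m)

    def test_ratio_features_scale_free(self, tiny_diary):
        """Multiplying all volumes by c > 0 leaves ratio features unchanged."""
        _, report, _, _ = run_qc(tiny_diary)
        c = 3.7
        scaled = replace(
            tiny_diary,
            voids=tuple(replace(v, volume=v.volume * c if v.volume else None,
                                post_void_residual=(v.post_void_residual * c
                                                    if v.post_void_residual else None))
                        for v in tiny_diary.voids),
            intakes=tuple(replace(e, volume=e.volume * c)
                          for e in tiny_diary.intakes))
        base = build_feature_vector(tiny_diary, report)
        big = build_feature_vector(scaled, report)
        for name in ("nocturnal_polyuria_ratio", "irritant_beverage_ratio",
                     "effective_voiding_rate"):
            assert big[name] == pytest.approx(base[name])


class TestPruneCollinear:
    @staticmethod
    def _matrix(n=50, seed=3):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({f"f{i}": rng.normal(size=n) for i in range(5)})

    def test_duplicate_column_dropped(self):
        m = self._matrix()
        m["f0_copy"] = m["f0"]
        kept, dropped = prune_collinear(m)
        assert "f0" in kept and "f0_copy" not in kept
        assert dropped["f0_copy"].startswith("collinear_with:f0")

    def test_negated_column_dropped(self):
        m = self._matrix()
        m["neg"] = -m["f1"]
        kept, dropped = prune_collinear(m)
        assert "neg" in dropped

    def test_independent_features_all_retained(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(200, 8)),
                         columns=[f"f{i}" for i in range(8)])
        kept, dropped = prune_collinear(m)
        assert dropped == {}
        assert kept == list(m.columns)

    def test_constant_column_degenerate(self):
        m = self._matrix()
        m["const"] = 1.0
        _, dropped = prune_collinear(m)
        assert dropped["const"] == "degenerate"

    def test_no_retained_pair_above_threshold(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=120)
        m = pd.DataFrame({
            "a": base, "b": base + 0.05 * rng.normal(size=120),
            "c": rng.normal(size=120), "d": -base + 0.05 * rng.normal(size=120)})
        kept, _ = prune_collinear(m, threshold=0.9)
        sub = m[kept].corr().abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.9


class TestStratifiedSplit:
    def test_single_stratum_exact_70_15_15(self):
        ids = [f"p{i}" for i in range(100)]
        split = stratified_split(ids, {i: "s" for i in ids}, seed=0)
        sizes = {p: len(split.ids(p)) for p in ("train", "validation", "test")}
        assert sizes == {"train": 70, "validation": 15, "test": 15}

    def test_deterministic_under_seed(self):
        ids = [f"p{i}" for i in range(10)]
        strata = {i: "s" for i in ids}
        a = stratified_split(ids, strata, seed=42)
        b = stratified_split(ids, strata, seed=42)
        assert a.partition == b.partition

    def test_two_strata_mix_preserved(self):
        ids = [f"p{i}" for i in range(100)]
        strata = {i: ("big" if k < 80 else "small") for k, i in enumerate(ids)}
        split = stratified_split(ids, strata, seed=1)
        for part, expect in (("train", 70), ("validation", 15), ("test", 15)):
            members = split.ids(part)
            assert len(members) == expect
            big = sum(1 for m in members if strata[m] == "big")
            assert abs(big / len(members) - 0.8) < 0.07

    def test_tiny_stratum_goes_to_train_with_warning(self):
        ids = ["a", "b", "c", "d", "e"]
        strata = {"a": "rare", "b": "rare", "c": "s", "d": "s", "e": "s"}
        with pytest.warns(UserWarning, match="rare"):
            split = stratified_split(ids, strata, seed=0)
        assert split.partition["a"] == split.partition["b"] == "train"


def test_feature_matrix_stacks_patients(small_cohort):
    vectors = []
    for d in small_cohort[:5]:
        clean, report, _, _ = run_qc(d)
        if not report.excluded:
            vectors.append(build_feature_vector(clean, report))
    m = feature_matrix(vectors)
    assert list(m.columns) == list(FEATURE_NAMES)
    assert len(m) == len(vectors)
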