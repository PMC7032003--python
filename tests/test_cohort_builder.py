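import numpy as np
import pandas as pd
import pytest

from akipair import (AKI, NON_AKI, EncounterRecord, LabSequence, WindowSpec,
                     apply_exclusion_criteria, balance_by_undersampling,
                     detect_aki_event, extract_window, filter_cohort,
                     split_selection_prediction)

from helpers import BASE, qualifying_pairs_brute, seq


def record(enc_id="E0", age=70.0, label=NON_AKI, anchor_hours=24 * 12,
           admission_hours=0.0, sequences=None):
    return EncounterRecord(
        encounter_id=enc_id, patient_id="P" + enc_id, age=age,
        admission=np.datetime64(BASE + pd.Timedelta(hours=admission_hours), "m"),
        discharge=np.datetime64(BASE + pd.Timedelta(hours=24 * 15), "m"),
        label=label,
        anchor=np.datetime64(BASE + pd.Timedelta(hours=anchor_hours), "m"),
        sequences=sequences or {},
    )


class TestDetectAkiEvent:
    def test_absolute_rise_boundary_qualifies(self):
        ev = detect_aki_event(seq([(0, 1.0), (24, 1.3)]))
        assert ev is not None and ev.time == np.datetime64(BASE + pd.Timedelta(hours=24), "m")

    def test_pair_outside_48h_does_not_qualify(self):
        assert detect_aki_event(seq([(0, 1.0), (49, 2.0)])) is None

    def test_ratio_rise_against_non_adjacent_measurement(self):
        # neither early pair qualifies; the 30 h reading does (e.g. via the
        # ratio 1.95/1.29 >= 1.5 against the 12 h point)
        s = seq([(0, 1.0), (12, 1.29), (30, 1.95)])
        ev = detect_aki_event(s)
        assert ev.time == np.datetime64(BASE + pd.Timedelta(hours=30), "m")
        assert ev.pair[1][1] == 1.95

    def test_event_matches_exhaustive_pair_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            hours = np.sort(rng.uniform(0, 200, size=8)).round(2)
            vals = rng.uniform(0.5, 1.6, size=8).round(2)
            s = seq(list(zip(hours, vals)))
            ev = detect_aki_event(s)
            pairs = qualifying_pairs_brute(s)
            if ev is None:
                assert pairs == []
            else:
                earliest_j = min(j for _, j in pairs)
                assert ev.time == s.times[earliest_j]
                # no qualifying second measurement precedes the event
                assert all(s.times[j] >= ev.time for _, j in pairs)

    def test_non_positive_creatinine_rejected(self):
        with pytest.raises(ValueError):
            detect_aki_event(seq([(0, 0.0), (10, 1.0)]))

    def test_ratio_cap_reads_band_literally(self):
        s = seq([(0, 0.4), (24, 0.9)])  # ratio 2.25, absolute rise 0.5 >= 0.3
        assert detect_aki_event(s) is not None
        s2 = seq([(0, 0.1), (24, 0.25)])  # ratio 2.5, rise only 0.15
        assert detect_aki_event(s2, ratio_cap=2.0) is None
        assert detect_aki_event(s2) is not None


class TestExclusionCriteria:
    def test_aki_eligible_with_prior_non_qualifying_pair(self):
        s = seq([(0, 1.0), (24, 1.1), (40, 1.5)])
        d = apply_exclusion_criteria(s, detect_aki_event(s))
        assert d.eligible and d.label == AKI

    def test_event_without_prior_pair_is_excluded(self):
        s = seq([(0, 1.0), (24, 1.4)])
        d = apply_exclusion_criteria(s, detect_aki_event(s))
        assert not d.eligible and d.reason == "no_pre_event_nonqualifying_pair"

    def test_no_pair_within_48h_is_excluded(self):
        s = seq([(0, 1.0), (100, 1.1)])
        d = apply_exclusion_criteria(s, detect_aki_event(s))
        assert not d.eligible and d.reason == "no_pair_within_48h"

    def test_non_aki_eligible_with_quiet_pair(self):
        s = seq([(0, 1.0), (24, 1.1)])
        d = apply_exclusion_criteria(s, detect_aki_event(s))
        assert d.eligible and d.label == NON_AKI

    def test_missing_creatinine_excluded(self):
        d = apply_exclusion_criteria(None, None)
        assert not d.eligible and d.reason == "no_creatinine"


class TestExtractWindow:
    def test_printed_two_day_horizon_example(self):
        anchor = pd.Timestamp("2010-08-25 14:00")
        rec = record(anchor_hours=(anchor - BASE).total_seconds() / 3600,
                     sequences={"X": seq([(0, 1.0)])})
        spec = WindowSpec(prediction_days=2, window_length_days=5)
        upper = rec.anchor - np.timedelta64(2 * 1440, "m")
        lower = upper - np.timedelta64(5 * 1440, "m")
        assert pd.Timestamp(lower) == pd.Timestamp("2010-08-18 14:00")
        assert pd.Timestamp(upper) == pd.Timestamp("2010-08-23 14:00")
        # and the implementation keeps exactly the points inside those bounds
        pts = [((upper - np.datetime64(BASE, "m")).astype(float) / 60 + h, v)
               for h, v in [(-5 * 24, 1.0), (-1, 2.0), (0, 3.0), (1, 4.0)]]
        rec = record(anchor_hours=(anchor - BASE).total_seconds() / 3600,
                     sequences={"X": seq(pts)})
        out = extract_window(rec, spec)
        assert list(out.sequences["X"].values) == [1.0, 2.0, 3.0]

    def test_zero_horizon_window_ends_at_anchor(self):
        rec = record(anchor_hours=240, sequences={"X": seq([(240, 9.0), (241, 1.0)])})
        out = extract_window(rec, WindowSpec(0, 5))
        assert list(out.sequences["X"].values) == [9.0]  # anchor point retained

    def test_empty_tests_dropped_from_sequence_map(self):
        rec = record(anchor_hours=240, sequences={"X": seq([(500, 1.0)])})
        out = extract_window(rec, WindowSpec(0, 5))
        assert out.sequences == {}

    def test_growing_horizon_never_adds_later_points(self):
        rec = record(anchor_hours=300,
                     sequences={"X": seq([(h, float(h)) for h in range(0, 300, 7)])})
        latest = None
        for d in range(6):
            out = extract_window(rec, WindowSpec(d, 5))
            if "X" not in out.sequences:
                continue
            newest = out.sequences["X"].times.max()
            if latest is not None:
                assert newest <= latest
            latest = newest


class TestFilterCohort:
    def test_age_boundary(self):
        recs = [record("A", age=59), record("B", age=60)]
        assert [r.encounter_id for r in filter_cohort(recs, 60, 0.001)] == ["B"]

    def test_stay_boundary_relative_to_anchor(self):
        recs = [record("A", anchor_hours=9.9 * 24), record("B", anchor_hours=10 * 24)]
        assert [r.encounter_id for r in filter_cohort(recs, 0, 10)] == ["B"]

    def test_empty_input(self):
        assert filter_cohort([]) == []


class TestBalancing:
    @staticmethod
    def make(n_pos, n_neg):
        return ([record(f"P{i}", label=AKI) for i in range(n_pos)]
                + [record(f"N{i}") for i in range(n_neg)])

    def test_floor_ratio_dataset_count_and_disjointness(self):
        datasets = balance_by_undersampling(self.make(10, 21), seed=0)
        assert len(datasets) == 2
        for ds in datasets:
            labels = [r.label for r in ds]
            assert labels.count(AKI) == labels.count(NON_AKI) == 10
        negs = [r.encounter_id for ds in datasets for r in ds if r.label != AKI]
        assert len(negs) == len(set(negs)) == 20  # disjoint, one left unused

    def test_equal_classes_give_single_full_dataset(self):
        datasets = balance_by_undersampling(self.make(7, 7), seed=1)
        assert len(datasets) == 1 and len(datasets[0]) == 14

    def test_reproducible_given_seed(self):
        a = balance_by_undersampling(self.make(5, 17), seed=9)
        b = balance_by_undersampling(self.make(5, 17), seed=9)
        assert [[r.encounter_id for r in ds] for ds in a] == \
               [[r.encounter_id for r in ds] for ds in b]

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balance_by_undersampling(self.make(5, 0), seed=0)


class TestSplit:
    def test_five_five_split_of_twenty(self):
        sel, pred = split_selection_prediction(TestBalancing.make(10, 10), 0.5, seed=0)
        assert len(sel) == len(pred) == 10

    def test_both_parts_stay_one_to_one(self):
        sel, pred = split_selection_prediction(TestBalancing.make(13, 13), 0.2, seed=3)
        for part in (sel, pred):
            labels = [r.label for r in part]
            assert labels.count(AKI) == labels.count(NON_AKI)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_selection_prediction(TestBalancing.make(5, 5), 1.0, seed=0)


class TestLabSequence:
    def test_duplicate_timestamps_keep_last_reported_value(self):
        t = BASE + pd.Timedelta(hours=1)
        s = LabSequence.from_points([(t, 1.0), (BASE, 0.5), (t, 2.0)])
        assert list(s.values) == [0.5, 2.0]
        assert (np.diff(s.times).astype(float) > 0).all()
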