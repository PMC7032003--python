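import numpy as np
import pandas as pd
import pytest
from scipy import stats

from akipair import (GeneratorConfig, LabSequence, build_cohort,
                     detect_aki_event, generate_cohort)

from helpers import qualifying_pairs_brute


def parse(cohort):
    enc = cohort.encounters.assign(
        admission_datetime=pd.to_datetime(cohort.encounters.admission_datetime),
        discharge_datetime=pd.to_datetime(cohort.encounters.discharge_datetime))
    labs = cohort.labs.assign(lab_datetime=pd.to_datetime(cohort.labs.lab_datetime))
    return enc, labs


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(GeneratorConfig(n_encounters=150, aki_prevalence=0.3,
                                           seed=42))


class TestDeterminism:
    def test_same_config_and_seed_give_identical_tables(self, cohort):
        again = generate_cohort(GeneratorConfig(n_encounters=150,
                                                aki_prevalence=0.3, seed=42))
        assert cohort.encounters.to_csv(index=False) == again.encounters.to_csv(index=False)
        assert cohort.labs.to_csv(index=False) == again.labs.to_csv(index=False)
        assert cohort.truth.to_csv(index=False) == again.truth.to_csv(index=False)

    def test_different_seeds_differ(self, cohort):
        other = generate_cohort(GeneratorConfig(n_encounters=150,
                                                aki_prevalence=0.3, seed=43))
        assert cohort.labs.to_csv(index=False) != other.labs.to_csv(index=False)


class TestPlantedLabels:
    def test_akin_labeler_recovers_every_planted_label_and_event_time(self, cohort):
        enc, labs = parse(cohort)
        records, audit = build_cohort(enc, labs, "CREA")
        assert len(records) == len(enc)  # every encounter eligible
        truth_label = dict(zip(cohort.truth.encounter_id, cohort.truth.planted_label))
        truth_event = dict(zip(cohort.truth.encounter_id,
                               cohort.truth.planted_event_datetime))
        for r in records:
            assert r.label == truth_label[r.encounter_id]
            if r.label == "AKI":
                assert pd.Timestamp(r.anchor) == pd.Timestamp(truth_event[r.encounter_id])

    def test_no_qualifying_pair_precedes_the_planted_event(self, cohort):
        enc, labs = parse(cohort)
        truth_event = dict(zip(cohort.truth.encounter_id,
                               cohort.truth.planted_event_datetime))
        aki_ids = set(cohort.truth.encounter_id[cohort.truth.planted_label == "AKI"])
        crea = labs[labs.lab_code == "CREA"]
        checked = 0
        for enc_id, grp in crea.groupby("encounter_id"):
            if enc_id not in aki_ids:
                continue
            s = LabSequence.from_points(zip(grp.lab_datetime, grp.value))
            event = np.datetime64(pd.Timestamp(truth_event[enc_id]), "m")
            for _, j in qualifying_pairs_brute(s):
                assert s.times[j] >= event
            checked += 1
        assert checked > 20

    def test_non_aki_creatinine_never_qualifies(self, cohort):
        enc, labs = parse(cohort)
        non_ids = set(cohort.truth.encounter_id[cohort.truth.planted_label != "AKI"])
        crea = labs[labs.lab_code == "CREA"]
        for enc_id, grp in crea.groupby("encounter_id"):
            if enc_id not in non_ids:
                continue
            s = LabSequence.from_points(zip(grp.lab_datetime, grp.value))
            assert detect_aki_event(s) is None


class TestCohortStructure:
    def test_prevalence_within_binomial_bounds(self, cohort):
        n = len(cohort.truth)
        k = (cohort.truth.planted_label == "AKI").sum()
        lo, hi = stats.binom.interval(0.99, n, 0.3)
        assert lo <= k <= hi

    def test_all_lab_times_within_stay(self, cohort):
        enc, labs = parse(cohort)
        m = labs.merge(enc, on="encounter_id")
        assert (m.lab_datetime >= m.admission_datetime).all()
        assert (m.lab_datetime <= m.discharge_datetime).all()

    def test_chronology_strictly_increasing_after_dedup(self, cohort):
        enc, labs = parse(cohort)
        for _, grp in labs.groupby(["encounter_id", "lab_code"]):
            s = LabSequence.from_points(zip(grp.lab_datetime, grp.value))
            if len(s) > 1:
                assert (np.diff(s.times).astype(float) > 0).all()

    def test_ages_respect_configured_range(self, cohort):
        assert cohort.encounters.age.between(60, 95).all()

    def test_informative_drift_present_only_with_effect(self):
        strong = generate_cohort(GeneratorConfig(n_encounters=120,
                                                 aki_prevalence=0.5, seed=9))
        null = generate_cohort(GeneratorConfig(n_encounters=120, aki_prevalence=0.5,
                                               effect_size=0.0, seed=9))
        def bun_gap(cohort):
            enc, labs = parse(cohort)
            truth = dict(zip(cohort.truth.encounter_id, cohort.truth.planted_label))
            bun = labs[labs.lab_code == "BUN"].merge(enc, on="encounter_id")
            last = bun.sort_values("lab_datetime").groupby("encounter_id").value.last()
            aki = last[[truth[e] == "AKI" for e in last.index]]
            non = last[[truth[e] != "AKI" for e in last.index]]
            return aki.mean() - non.mean()
        assert bun_gap(strong) > 8.0
        assert abs(bun_gap(null)) < 3.0


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"n_encounters": 0},
        {"aki_prevalence": 0.0},
        {"aki_prevalence": 1.0},
        {"measurements_per_day": -1},
        {"effect_size": -0.5},
        {"panel": ("BUN", "WBC")},          # creatinine missing
        {"panel": ("CREA", "BUN", "BUN")},  # duplicate code
        {"age_range": (80, 60)},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorConfig(**kw)
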