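"""Synthetic inpatient encounter and laboratory-event generator.

Emulates the statistical shape of an older-inpatient EHR extract: ~10% AKI
prevalence, multi-day stays, irregularly timed laboratory panels, serum
creatinine trajectories that do or do not cross the AKIN stage-1 thresholds,
and an upward pre-event drift in the informative analytes (creatinine and
blood urea nitrogen) so the trend representation has a recoverable signal.

Label correctness is guaranteed by construction, in two steps per encounter:

1. a forward *sweep* caps every creatinine value below both stage-1
   thresholds relative to all values in the preceding 48 h (with margins wide
   enough that 2-decimal CSV rounding cannot re-cross a threshold), so the
   swept region contains no qualifying pair;
2. for AKI encounters an explicit qualifying pair (rise of 0.35 mg/dL) is
   planted at the intended event time, after the sweep, so the earliest
   qualifying second measurement is exactly the planted one.

Measurement times follow a homogeneous Poisson process per test, truncated to
the stay.  Values are a per-test Gaussian baseline plus a per-encounter
offset (between-patient variation) plus measurement noise, with a linear ramp
over the 5 days before the planted event for the informative analytes.
Non-informative panel members are pure noise, exercising the selection
stage's ability to discard useless channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["CREATININE_CODE", "BUN_CODE", "GeneratorConfig", "SyntheticCohort",
           "generate_cohort"]

CREATININE_CODE = "CREA"
BUN_CODE = "BUN"

DATETIME_FMT = "%Y-%m-%d %H:%M"

# (baseline mean, between-encounter sd, within-encounter sd) per analyte;
# unknown codes fall back to a generic noise analyte.
_BASELINES: Dict[str, Tuple[float, float, float]] = {
    CREATININE_CODE: (0.9, 0.25, 0.05),
    BUN_CODE: (18.0, 5.0, 0.6),
    "WBC": (8.0, 1.8, 0.9),
    "HGB": (12.5, 1.2, 0.5),
    "PLT": (250.0, 45.0, 18.0),
    "NA": (140.0, 2.5, 1.5),
    "K": (4.2, 0.35, 0.2),
    "GLU": (115.0, 20.0, 12.0),
}
_DEFAULT_BASELINE = (100.0, 10.0, 5.0)

# total pre-event rise of the informative analytes over the ramp, at
# effect_size = 1 (mg/dL); the ramp is linear over RAMP_DAYS before the event
# and holds at its peak afterwards.
_RAMP_TOTALS = {CREATININE_CODE: 0.25, BUN_CODE: 15.0}
RAMP_DAYS = 5.0

# refractory period between successive draws of the same test: repeat labs
# are not redrawn within minutes of each other, and it bounds the noise
# contribution to slopes (which scales with 1/dt)
DEAD_TIME_MIN = 120.0

# AKIN stage-1 thresholds with safety margins used by the sweep; the margins
# absorb the 2-decimal rounding of written values.
_AKIN_DELTA = 0.3
_AKIN_RATIO = 1.5
_SWEEP_DELTA = _AKIN_DELTA - 0.02
_SWEEP_RATIO = _AKIN_RATIO - 0.05
_PAIR_WINDOW_MIN = 48 * 60
_PLANTED_RISE = 0.35

_EPOCH = pd.Timestamp("2010-01-01 00:00")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    effect_size scales the pre-event drift of the informative analytes
    (0 = null data); noise_sd scales the within-encounter measurement noise.
    min_stay_days must cover the longest window + horizon used downstream
    (10 days for the default 5-day window and 5-day maximum horizon).
    """

    n_encounters: int = 800
    aki_prevalence: float = 0.1054
    age_range: Tuple[int, int] = (60, 95)
    panel: Tuple[str, ...] = (CREATININE_CODE, BUN_CODE, "WBC", "HGB",
                              "PLT", "NA", "K", "GLU")
    measurements_per_day: float = 2.0
    min_stay_days: float = 10.0
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encounters <= 0:
            raise ValueError("n_encounters must be positive")
        if not 0 < self.aki_prevalence < 1:
            raise ValueError("aki_prevalence must lie in (0, 1)")
        if self.measurements_per_day <= 0:
            raise ValueError("measurements_per_day must be positive")
        if self.min_stay_days <= 0:
            raise ValueError("min_stay_days must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(set(self.panel)) != len(self.panel):
            raise ValueError("panel codes must be unique")
        if CREATININE_CODE not in self.panel:
            raise ValueError(f"panel must include the creatinine code {CREATININE_CODE!r}")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be (min, max) with min <= max")


class SyntheticCohort(NamedTuple):
    encounters: pd.DataFrame   # encounter_id, patient_id, age, admission/discharge datetimes
    labs: pd.DataFrame         # encounter_id, lab_code, lab_datetime, value
    truth: pd.DataFrame        # encounter_id, planted_label, planted_event_datetime

    def write_csvs(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.encounters.to_csv(d / "encounters.csv", index=False)
        self.labs.to_csv(d / "labs.csv", index=False)
        self.truth.to_csv(d / "ground_truth.csv", index=False)


def _poisson_times(rng: np.random.Generator, rate_per_day: float,
                   start_min: float, end_min: float) -> np.ndarray:
    """Homogeneous Poisson event times with a dead time, truncated to the stay."""
    span_days = (end_min - start_min) / 1440.0
    n = rng.poisson(rate_per_day * span_days)
    t = np.unique(np.round(np.sort(rng.uniform(start_min, end_min, size=n))))
    kept: List[float] = []
    for x in t:  # enforce the refractory period
        if not kept or x - kept[-1] >= DEAD_TIME_MIN:
            kept.append(x)
    return np.asarray(kept)


def _sweep_below_thresholds(times_min: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Cap values so no ordered pair within 48 h qualifies as stage 1."""
    v = values.copy()
    for j in range(1, len(v)):
        cap = np.inf
        for i in range(j):
            if times_min[j] - times_min[i] <= _PAIR_WINDOW_MIN:
                cap = min(cap, v[i] + _SWEEP_DELTA, v[i] * _SWEEP_RATIO)
        if v[j] > cap:
            v[j] = cap
    return v


def _merge_planted(times_min: np.ndarray, planted: Sequence[float]) -> np.ndarray:
    """Union of sampled and planted times, minute precision.

    Sampled points within the dead time of a planted point are dropped so the
    refractory spacing survives the merge.
    """
    p = np.round(np.asarray(planted, dtype=float))
    if times_min.size:
        near = np.min(np.abs(times_min[:, None] - p[None, :]), axis=1) < DEAD_TIME_MIN
        times_min = times_min[~near]
    return np.unique(np.concatenate([times_min, p]))


def generate_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    """Generate encounter, laboratory and ground-truth tables.

    Deterministic given ``cfg`` (including its seed): the same configuration
    always yields byte-identical tables.  Exactly round(n x prevalence)
    encounters are designated AKI, assigned by a seeded permutation, so the
    class counts of the study conditions are met exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_encounters
    n_aki = int(round(n * cfg.aki_prevalence))
    n_aki = min(max(n_aki, 1), n - 1)  # keep both classes represented
    is_aki = np.zeros(n, dtype=bool)
    is_aki[rng.permutation(n)[:n_aki]] = True

    enc_rows: List[dict] = []
    lab_rows: List[dict] = []
    truth_rows: List[dict] = []
    width = len(str(n))

    for i in range(n):
        enc_id = f"E{i:0{width}d}"
        age = int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
        admission = float(np.round(rng.uniform(0, 365 * 1440)))  # minutes from epoch
        if is_aki[i]:
            event = admission + np.round(
                (cfg.min_stay_days + rng.uniform(0.0, 3.0)) * 1440)
            anchor_target = event
            discharge = event + np.round(rng.uniform(3.0, 5.0) * 1440)
        else:
            event = None
            anchor_target = admission + np.round(
                (cfg.min_stay_days + rng.uniform(0.0, 3.0)) * 1440)
            discharge = anchor_target + np.round(rng.uniform(0.5, 2.0) * 1440)

        for code in cfg.panel:
            base_mu, between_sd, within_sd = _BASELINES.get(code, _DEFAULT_BASELINE)
            offset = rng.normal(0.0, between_sd)
            times = _poisson_times(rng, cfg.measurements_per_day, admission, discharge)
            if code == CREATININE_CODE:
                if is_aki[i]:
                    # guarantee a pre-event non-qualifying pair within 48 h and
                    # a predecessor within 48 h of the event itself
                    times = _merge_planted(times, [event - 44 * 60,
                                                   event - 24 * 60, event])
                else:
                    # anchor = last creatinine; plant a 48 h pair ending there
                    times = times[times <= anchor_target]
                    times = _merge_planted(times, [anchor_target - 24 * 60,
                                                   anchor_target])
            if times.size == 0:
                continue

            values = base_mu + offset + rng.normal(0.0, within_sd * cfg.noise_sd,
                                                   size=times.size)
            if is_aki[i] and code in _RAMP_TOTALS and cfg.effect_size > 0:
                ramp_start = event - RAMP_DAYS * 1440
                frac = np.clip((times - ramp_start) / (RAMP_DAYS * 1440), 0.0, 1.0)
                values = values + _RAMP_TOTALS[code] * cfg.effect_size * frac

            if code == CREATININE_CODE:
                values = np.maximum(values, 0.3)  # physiological floor, keeps ratios sane
                if is_aki[i]:
                    pre = times < event
                    values[pre] = _sweep_below_thresholds(times[pre], values[pre])
                    j_event = int(np.searchsorted(times, event))
                    # latest predecessor within 48 h (the planted -24 h point at worst)
                    preds = np.nonzero(pre & (event - times <= _PAIR_WINDOW_MIN))[0]
                    v_prev = values[preds[-1]]
                    values[j_event] = v_prev + _PLANTED_RISE
                    post = times > event
                    values[post] = np.maximum(values[post], values[j_event])
                else:
                    values = _sweep_below_thresholds(times, values)

            for t, v in zip(times, values):
                lab_rows.append({
                    "encounter_id": enc_id,
                    "lab_code": code,
                    "lab_datetime": _fmt(t),
                    "value": round(float(v), 2),
                })

        enc_rows.append({
            "encounter_id": enc_id,
            "patient_id": f"P{i:0{width}d}",
            "age": age,
            "admission_datetime": _fmt(admission),
            "discharge_datetime": _fmt(discharge),
        })
        truth_rows.append({
            "encounter_id": enc_id,
            "planted_label": "AKI" if is_aki[i] else "non-AKI",
            "planted_event_datetime": _fmt(event) if event is not None else "",
        })

    encounters = pd.DataFrame(enc_rows)
    labs = pd.DataFrame(lab_rows).sort_values(
        ["encounter_id", "lab_code", "lab_datetime"], kind="stable"
    ).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(encounters, labs, truth)


def _fmt(minutes_from_epoch: float) -> str:
    ts = _EPOCH + pd.Timedelta(minutes=int(round(minutes_from_epoch)))
    return ts.strftime(DATETIME_FMT)
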