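"""Cohort construction: AKIN stage-1 labeling, exclusions, windows, balancing.

An encounter is labeled AKI when two serum-creatinine measurements taken at
most 48 h apart show an absolute rise of at least 0.3 mg/dL or a rise to at
least 150% of the earlier value (AKIN stage 1).  The anchor of an AKI
encounter is the AKI Time — the timestamp of the second measurement of the
earliest qualifying pair; the anchor of a non-AKI encounter is the time of its
last creatinine measurement.  All ordered measurement pairs within 48 h are
considered, not only adjacent ones, and the 48 h bound is inclusive on exact
minute-precision timestamps.

Eligibility further requires, for AKI encounters, at least one non-qualifying
creatinine pair within 48 h strictly before the event (the patient verifiably
did not present with AKI), and for non-AKI encounters at least one creatinine
pair within 48 h (the rule had a real chance to fire).

Prediction-time windows are [anchor - (w + d) days, anchor - d days] for
window length w and horizon d, closed at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "AKI",
    "NON_AKI",
    "LabSequence",
    "EncounterRecord",
    "WindowSpec",
    "AkiEvent",
    "Eligibility",
    "detect_aki_event",
    "apply_exclusion_criteria",
    "build_cohort",
    "extract_window",
    "filter_cohort",
    "balance_by_undersampling",
    "split_selection_prediction",
]

AKI = "AKI"
NON_AKI = "non-AKI"

_PAIR_WINDOW = np.timedelta64(48 * 60, "m")
_EPS = 1e-9

# machine-readable exclusion reason codes
REASON_OK_AKI = "ok_aki"
REASON_OK_NON_AKI = "ok_non_aki"
REASON_NO_CREATININE = "no_creatinine"
REASON_NO_PAIR_WITHIN_48H = "no_pair_within_48h"
REASON_NO_PRE_EVENT_NONQUALIFYING_PAIR = "no_pre_event_nonqualifying_pair"


@dataclass(frozen=True)
class LabSequence:
    """Chronologically ordered (time, value) points of one test in one encounter."""

    times: np.ndarray   # datetime64, strictly increasing
    values: np.ndarray  # float

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_points(cls, points: Iterable[Tuple[object, float]]) -> "LabSequence":
        """Build from (timestamp, value) pairs.

        Timestamps are floored to minute precision; duplicate timestamps keep
        the last-reported value, so the result is strictly increasing in time.
        """
        dedup: Dict[np.datetime64, float] = {}
        for t, v in points:
            dedup[np.datetime64(pd.Timestamp(t)).astype("datetime64[m]")] = float(v)
        if not dedup:
            return cls(np.empty(0, dtype="datetime64[m]"), np.empty(0))
        times = np.array(sorted(dedup), dtype="datetime64[m]")
        values = np.array([dedup[t] for t in times])
        return cls(times, values)


@dataclass(frozen=True)
class EncounterRecord:
    """One hospital admission — the unit of classification."""

    encounter_id: str
    patient_id: str
    age: float
    admission: np.datetime64
    discharge: np.datetime64
    label: str                       # AKI / non-AKI
    anchor: np.datetime64            # AKI Time, or last creatinine time
    sequences: Dict[str, LabSequence] = field(default_factory=dict)


@dataclass(frozen=True)
class WindowSpec:
    """Data-collection window: length w days ending d days before the anchor."""

    prediction_days: int = 0
    window_length_days: int = 5

    def __post_init__(self) -> None:
        if self.prediction_days < 0:
            raise ValueError("prediction_days must be >= 0")
        if self.window_length_days <= 0:
            raise ValueError("window_length_days must be > 0")


@dataclass(frozen=True)
class AkiEvent:
    time: np.datetime64                     # AKI Time (second measurement)
    pair: Tuple[Tuple[np.datetime64, float], Tuple[np.datetime64, float]]


@dataclass(frozen=True)
class Eligibility:
    eligible: bool
    label: Optional[str]
    reason: str


def _qualifies(v_i: float, v_j: float, delta: float, ratio: float,
               ratio_cap: Optional[float]) -> bool:
    if v_j - v_i >= delta - _EPS:
        return True
    r = v_j / v_i
    if r >= ratio - _EPS:
        return ratio_cap is None or r <= ratio_cap + _EPS
    return False


def detect_aki_event(
    creatinine: LabSequence,
    delta: float = 0.3,
    ratio: float = 1.5,
    pair_window_hours: float = 48.0,
    ratio_cap: Optional[float] = None,
) -> Optional[AkiEvent]:
    """Earliest AKIN stage-1 qualifying creatinine pair, if any.

    Scans all ordered measurement pairs (i, j), i < j, with t_j - t_i at most
    ``pair_window_hours`` (inclusive), and returns the event anchored at the
    earliest qualifying second measurement.  ``ratio_cap`` optionally reads
    the 150-200% band literally, disqualifying ratio rises above the cap
    (absolute rises are unaffected); it is off by default.
    """
    t, v = creatinine.times, creatinine.values
    if np.any(v <= 0):
        raise ValueError("creatinine values must be positive")
    window = np.timedelta64(int(round(pair_window_hours * 60)), "m")
    n = len(t)
    for j in range(1, n):
        for i in range(j):
            if t[j] - t[i] > window:
                continue
            if _qualifies(v[i], v[j], delta, ratio, ratio_cap):
                return AkiEvent(time=t[j], pair=((t[i], v[i]), (t[j], v[j])))
    return None


def _has_pair_within(creatinine: LabSequence, window: np.timedelta64,
                     before: Optional[np.datetime64] = None,
                     nonqualifying: bool = False,
                     delta: float = 0.3, ratio: float = 1.5,
                     ratio_cap: Optional[float] = None) -> bool:
    t, v = creatinine.times, creatinine.values
    for j in range(1, len(t)):
        if before is not None and t[j] >= before:
            break
        for i in range(j):
            if t[j] - t[i] > window:
                continue
            if not nonqualifying or not _qualifies(v[i], v[j], delta, ratio, ratio_cap):
                return True
    return False


def apply_exclusion_criteria(
    creatinine: Optional[LabSequence],
    event: Optional[AkiEvent],
    delta: float = 0.3,
    ratio: float = 1.5,
    pair_window_hours: float = 48.0,
    ratio_cap: Optional[float] = None,
) -> Eligibility:
    """Decide eligibility and label for one encounter.

    AKI-eligible: a qualifying event exists and at least one non-qualifying
    pair within 48 h ends strictly before the event time.  Non-AKI-eligible:
    no event exists but at least one pair within 48 h does.  Everything else
    is excluded with a machine-readable reason.
    """
    if creatinine is None or len(creatinine) == 0:
        return Eligibility(False, None, REASON_NO_CREATININE)
    window = np.timedelta64(int(round(pair_window_hours * 60)), "m")
    if event is not None:
        ok = _has_pair_within(creatinine, window, before=event.time,
                              nonqualifying=True, delta=delta, ratio=ratio,
                              ratio_cap=ratio_cap)
        if ok:
            return Eligibility(True, AKI, REASON_OK_AKI)
        return Eligibility(False, None, REASON_NO_PRE_EVENT_NONQUALIFYING_PAIR)
    if _has_pair_within(creatinine, window):
        return Eligibility(True, NON_AKI, REASON_OK_NON_AKI)
    return Eligibility(False, None, REASON_NO_PAIR_WITHIN_48H)


def build_cohort(
    encounters: pd.DataFrame,
    labs: pd.DataFrame,
    creatinine_code: str,
    delta: float = 0.3,
    ratio: float = 1.5,
    pair_window_hours: float = 48.0,
    ratio_cap: Optional[float] = None,
) -> Tuple[List[EncounterRecord], pd.DataFrame]:
    """Label and anchor every encounter; report exclusions.

    Returns the eligible records plus a per-encounter audit table
    (encounter_id, label, anchor_datetime, exclusion_reason) covering all
    input encounters, eligible or not.
    """
    seq_map: Dict[str, Dict[str, LabSequence]] = {}
    for (enc_id, code), grp in labs.groupby(["encounter_id", "lab_code"], sort=True):
        seq_map.setdefault(str(enc_id), {})[str(code)] = LabSequence.from_points(
            zip(grp["lab_datetime"], grp["value"])
        )
    records: List[EncounterRecord] = []
    audit_rows = []
    for row in encounters.sort_values("encounter_id").itertuples(index=False):
        enc_id = str(row.encounter_id)
        sequences = seq_map.get(enc_id, {})
        crea = sequences.get(creatinine_code)
        event = None
        if crea is not None and len(crea) > 0:
            event = detect_aki_event(crea, delta=delta, ratio=ratio,
                                     pair_window_hours=pair_window_hours,
                                     ratio_cap=ratio_cap)
        decision = apply_exclusion_criteria(crea, event, delta=delta, ratio=ratio,
                                            pair_window_hours=pair_window_hours,
                                            ratio_cap=ratio_cap)
        anchor = None
        if decision.eligible:
            anchor = event.time if decision.label == AKI else crea.times[-1]
            records.append(EncounterRecord(
                encounter_id=enc_id,
                patient_id=str(row.patient_id),
                age=float(row.age),
                admission=np.datetime64(pd.Timestamp(row.admission_datetime)).astype("datetime64[m]"),
                discharge=np.datetime64(pd.Timestamp(row.discharge_datetime)).astype("datetime64[m]"),
                label=decision.label,
                anchor=anchor,
                sequences=sequences,
            ))
        audit_rows.append({
            "encounter_id": enc_id,
            "label": decision.label if decision.eligible else "",
            "anchor_datetime": pd.Timestamp(anchor).strftime("%Y-%m-%d %H:%M") if anchor is not None else "",
            "exclusion_reason": decision.reason,
        })
    return records, pd.DataFrame(audit_rows)


def extract_window(record: EncounterRecord, spec: WindowSpec) -> EncounterRecord:
    """Restrict every sequence to [anchor - (w+d), anchor - d] days, inclusive.

    Tests left with no points inside the window are dropped from the sequence
    map; an encounter may legitimately end with zero sequences.
    """
    upper = record.anchor - np.timedelta64(spec.prediction_days * 1440, "m")
    lower = upper - np.timedelta64(spec.window_length_days * 1440, "m")
    windowed: Dict[str, LabSequence] = {}
    for code, seq in record.sequences.items():
        mask = (seq.times >= lower) & (seq.times <= upper)
        if mask.any():
            windowed[code] = LabSequence(seq.times[mask], seq.values[mask])
    return replace(record, sequences=windowed)


def filter_cohort(
    records: Iterable[EncounterRecord],
    min_age: float = 60.0,
    min_stay_days: float = 10.0,
) -> List[EncounterRecord]:
    """Keep encounters aged >= min_age with anchor - admission >= min_stay_days."""
    min_stay = np.timedelta64(int(round(min_stay_days * 1440)), "m")
    return [r for r in records
            if r.age >= min_age and (r.anchor - r.admission) >= min_stay]


def balance_by_undersampling(
    records: Sequence[EncounterRecord],
    seed: int,
) -> List[List[EncounterRecord]]:
    """Repeated disjoint random under-sampling to 1:1 class balance.

    Produces floor(n_neg / n_pos) datasets; each contains every AKI record
    plus n_pos non-AKI records drawn without replacement, disjoint across
    datasets.  Leftover negatives are unused.
    """
    pos = [r for r in records if r.label == AKI]
    neg = [r for r in records if r.label != AKI]
    if not pos or not neg:
        raise ValueError("both classes must be non-empty to balance")
    n_sets = len(neg) // len(pos)
    if n_sets == 0:
        raise ValueError(
            f"cannot balance: {len(neg)} non-AKI < {len(pos)} AKI records")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(neg))
    datasets = []
    for s in range(n_sets):
        chunk = [neg[i] for i in order[s * len(pos):(s + 1) * len(pos)]]
        datasets.append(pos + chunk)
    return datasets


def split_selection_prediction(
    dataset: Sequence[EncounterRecord],
    prediction_fraction: float,
    seed: int,
) -> Tuple[List[EncounterRecord], List[EncounterRecord]]:
    """Stratified split of a balanced dataset into selection/prediction parts.

    The prediction part receives floor(fraction x class size) records per
    class; the selection part gets the remainder, so both parts stay 1:1.
    """
    if not 0 < prediction_fraction < 1:
        raise ValueError("prediction_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    selection: List[EncounterRecord] = []
    prediction: List[EncounterRecord] = []
    for lab in (AKI, NON_AKI):
        cls = sorted((r for r in dataset if r.label == lab),
                     key=lambda r: r.encounter_id)
        order = rng.permutation(len(cls))
        n_pred = int(prediction_fraction * len(cls))
        pred_idx = set(order[:n_pred].tolist())
        for i, r in enumerate(cls):
            (prediction if i in pred_idx else selection).append(r)
    return selection, prediction
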