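"""Symbolic representations of laboratory-value sequences.

Each laboratory test contributes two feature channels per encounter:

* LAST — the final value of the sequence, discretized into one of six symbols
  by mean/standard-deviation breakpoints fitted on a reference population;
* TREND — the sequence of slopes between adjacent measurements (value change
  per day, computed from minute-precision timestamps), each slope discretized
  with breakpoints fitted on the pooled slopes of the population.

The six bins are bounded by mu-sigma, mu-sigma/2, mu, mu+sigma/2, mu+sigma,
every boundary belonging to the lower symbol.  Slopes are carried at full
precision; rounding them before computing similarities would change DTW
distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Dict, Iterable, List, Optional, Tuple

import numpy as np

from .classifier import LAST, TREND, PairId

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_builder import EncounterRecord, LabSequence

__all__ = [
    "SymbolizerParams",
    "last_value",
    "slope_sequence",
    "fit_symbolizer",
    "symbolize",
    "symbolize_slopes",
    "fit_pair_symbolizers",
    "build_payloads",
]

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class SymbolizerParams:
    """Mean and standard deviation defining the six symbol bins."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def last_value(sequence: "LabSequence") -> Optional[float]:
    """Final value v_n of the sequence, or None when the sequence is empty."""
    if len(sequence) == 0:
        return None
    return float(sequence.values[-1])


def slope_sequence(sequence: "LabSequence") -> np.ndarray:
    """Slopes between adjacent measurements, in value change per day.

    Time differences are taken in minutes and converted to days (1440 minutes
    per day).  A sequence with fewer than two points yields an empty array,
    signalling that the trend representation is missing.
    """
    if len(sequence) < 2:
        return np.empty(0)
    dt_min = np.diff(sequence.times).astype("timedelta64[m]").astype(float)
    if np.any(dt_min <= 0):
        raise ValueError("timestamps must be strictly increasing (deduplicate upstream)")
    return np.diff(sequence.values) / (dt_min / MINUTES_PER_DAY)


def fit_symbolizer(values: Iterable[float]) -> SymbolizerParams:
    """Fit bin parameters: arithmetic mean and sample (n-1) standard deviation.

    A single observation gives sigma = 0 (the degenerate one-bin case).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot fit a symbolizer on an empty collection")
    sigma = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return SymbolizerParams(mu=float(np.mean(arr)), sigma=sigma)


def symbolize(x: float, p: SymbolizerParams) -> int:
    """Map a value to its 6-level symbol.

    Boundaries mu-sigma, mu-sigma/2, mu, mu+sigma/2, mu+sigma belong to the
    lower symbol.  With sigma = 0 all bins collapse onto mu and every value
    maps to symbol 3.
    """
    if p.sigma == 0:
        return 3
    mu, s = p.mu, p.sigma
    if x <= mu - s:
        return 1
    if x <= mu - s / 2:
        return 2
    if x <= mu:
        return 3
    if x <= mu + s / 2:
        return 4
    if x <= mu + s:
        return 5
    return 6


def symbolize_slopes(slopes: np.ndarray, p: SymbolizerParams) -> Tuple[int, ...]:
    """Element-wise symbolization of a slope sequence (empty in, empty out)."""
    return tuple(symbolize(float(s), p) for s in slopes)


# ---------------------------------------------------------------------------
# Cohort-level helpers: fit per-(test, type) symbolizers and build the
# per-encounter payload map consumed by the classifier.
# ---------------------------------------------------------------------------

def fit_pair_symbolizers(
    records: Iterable["EncounterRecord"],
) -> Dict[PairId, SymbolizerParams]:
    """Fit one symbolizer per (laboratory test, type) pair over a population.

    LAST parameters are fitted on the last values of every encounter that has
    the test; TREND parameters on the pooled slopes of all those encounters.
    Pairs with no data in the population are simply absent from the result
    (downstream classification abstains on them).
    """
    last_vals: Dict[str, List[float]] = {}
    slope_vals: Dict[str, List[float]] = {}
    for rec in records:
        for code, seq in rec.sequences.items():
            v = last_value(seq)
            if v is not None:
                last_vals.setdefault(code, []).append(v)
            s = slope_sequence(seq)
            if s.size:
                slope_vals.setdefault(code, []).extend(s.tolist())
    params: Dict[PairId, SymbolizerParams] = {}
    for code, vals in last_vals.items():
        params[PairId(code, LAST)] = fit_symbolizer(vals)
    for code, vals in slope_vals.items():
        params[PairId(code, TREND)] = fit_symbolizer(vals)
    return params


def build_payloads(
    records: Iterable["EncounterRecord"],
    params: Dict[PairId, SymbolizerParams],
) -> Dict[str, Dict[PairId, object]]:
    """Symbolized feature payloads per encounter.

    Returns ``{encounter_id: {pair: payload}}`` where the payload is an int
    symbol for LAST pairs and a tuple of symbols for TREND pairs.  Pairs whose
    representation is missing for an encounter (test absent, or single-point
    sequence for TREND) are omitted, which the classifier reads as abstain.
    """
    out: Dict[str, Dict[PairId, object]] = {}
    for rec in records:
        payloads: Dict[PairId, object] = {}
        for code, seq in rec.sequences.items():
            p_last = params.get(PairId(code, LAST))
            if p_last is not None:
                v = last_value(seq)
                if v is not None:
                    payloads[PairId(code, LAST)] = symbolize(v, p_last)
            p_trend = params.get(PairId(code, TREND))
            if p_trend is not None:
                s = slope_sequence(seq)
                if s.size:
                    payloads[PairId(code, TREND)] = symbolize_slopes(s, p_trend)
        out[rec.encounter_id] = payloads
    return out
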