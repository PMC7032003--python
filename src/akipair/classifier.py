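"""Per-(laboratory test, type) KNN classification and OR fusion.

Each feature channel — a PairId, i.e. a laboratory test under its LAST or
TREND representation — votes independently: the target's payload is compared
to every labeled reference possessing the same channel (symbol difference for
LAST, DTW distance for TREND), the K nearest references vote, and the channel
returns positive, negative, or abstain.  A set of channels is fused with an
OR rule: the patient is called positive if any channel votes positive;
abstains count as negative evidence.  The continuous score used for ROC
analysis is the maximum positive-neighbor fraction over the voting channels —
an explicit scoring convention layered on top of the binary fused rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, NamedTuple, Optional, Sequence, Tuple

from .similarity import dtw_distance, last_value_similarity

__all__ = [
    "LAST",
    "TREND",
    "PairId",
    "KnnConfig",
    "PairVote",
    "POSITIVE",
    "NEGATIVE",
    "ABSTAIN",
    "pair_distance",
    "pair_knn_classify",
    "or_fuse",
    "score",
]

LAST = "LAST"
TREND = "TREND"

POSITIVE = "positive"
NEGATIVE = "negative"
ABSTAIN = "abstain"


class PairId(NamedTuple):
    """One feature channel: a laboratory test code plus a representation type."""

    lab_code: str
    rep_type: str


@dataclass(frozen=True)
class KnnConfig:
    """KNN voting configuration.

    k : neighbor count (odd values avoid most vote ties).
    tie_vote : label returned on an exact vote tie; the positive default
        favors sensitivity, the usual preference in clinical screening.
    min_neighbors : smallest usable reference count before the channel
        abstains; with fewer than k (but >= min_neighbors) references all of
        them vote.
    """

    k: int = 5
    tie_vote: str = POSITIVE
    min_neighbors: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tie_vote not in (POSITIVE, NEGATIVE):
            raise ValueError("tie_vote must be 'positive' or 'negative'")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")


class PairVote(NamedTuple):
    vote: str
    positive_fraction: Optional[float]


def pair_distance(pair: PairId, payload_a, payload_b) -> float:
    """Distance between two payloads of the same channel (LS or TS)."""
    if pair.rep_type == LAST:
        return float(last_value_similarity(payload_a, payload_b))
    if pair.rep_type == TREND:
        return dtw_distance(payload_a, payload_b)
    raise ValueError(f"unknown representation type {pair.rep_type!r}")


def _majority(pos: int, total: int, cfg: KnnConfig) -> PairVote:
    frac = pos / total
    if 2 * pos > total:
        return PairVote(POSITIVE, frac)
    if 2 * pos < total:
        return PairVote(NEGATIVE, frac)
    return PairVote(cfg.tie_vote, frac)


def pair_knn_classify(
    target_payload,
    references: Sequence[Tuple[str, object, bool]],
    pair: PairId,
    cfg: KnnConfig,
) -> PairVote:
    """Vote of one channel on one target patient.

    Parameters
    ----------
    target_payload
        The target's payload for this channel, or None when missing.
    references
        ``(encounter_id, payload, is_positive)`` triples, restricted to
        references that possess this channel's representation.

    Notes
    -----
    References are ranked by ascending distance with the encounter id as the
    final tie-break key, so classification is deterministic; exactly k are
    taken (all of them when fewer than k but at least ``min_neighbors``
    exist).  A missing target payload or an empty reference set yields
    abstain.
    """
    if target_payload is None or len(references) < cfg.min_neighbors:
        return PairVote(ABSTAIN, None)
    ranked = sorted(
        ((pair_distance(pair, target_payload, payload), enc_id, label)
         for enc_id, payload, label in references),
    )
    top = ranked[: cfg.k]
    pos = sum(1 for _, _, label in top if label)
    return _majority(pos, len(top), cfg)


def or_fuse(pair_votes: Mapping[PairId, str]) -> str:
    """Fuse channel votes: positive iff any channel voted positive.

    Abstains count as negative; an empty map (no evidence) is negative.
    """
    for vote in pair_votes.values():
        if vote == POSITIVE:
            return POSITIVE
    return NEGATIVE


def score(
    pair_votes: Mapping[PairId, str],
    pair_fracs: Mapping[PairId, Optional[float]],
) -> float:
    """Continuous risk score in [0, 1] for ROC analysis.

    The maximum positive-neighbor fraction over non-abstaining channels;
    0 when every channel abstains.
    """
    best = 0.0
    for pair, vote in pair_votes.items():
        if vote == ABSTAIN:
            continue
        frac = pair_fracs.get(pair)
        if frac is not None and frac > best:
            best = frac
    return best
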