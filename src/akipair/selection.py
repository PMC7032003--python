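"""Greedy selection of the most effective (laboratory test, type) pairs.

Candidate channels are scored by the accuracy of the OR-fused KNN classifier
on the selection part of a balanced dataset.  Because each channel votes
independently, its leave-one-out vote for every selection-part encounter is
computed once; evaluating any channel subset then reduces to OR-ing boolean
vote vectors, which makes sequential forward selection (SFS) and sequential
backward selection (SBS) cheap even with many candidates.

SFS starts from the empty set and keeps adding the accuracy-maximizing
channel while the accuracy strictly improves (OR fusion accumulates false
positives, so the loop terminates naturally).  SBS starts from the full set,
repeatedly removes the channel whose exclusion maximizes accuracy down to a
single channel, and returns the best subset seen along the way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .classifier import (
    ABSTAIN,
    LAST,
    KnnConfig,
    PairId,
    PairVote,
    _majority,
    dtw_distance,
)

__all__ = [
    "SelectionResult",
    "pair_vote_table",
    "pair_vote_table_against",
    "evaluate_pair_set",
    "sfs",
    "sbs",
]

Payloads = Mapping[str, Mapping[PairId, object]]


@dataclass(frozen=True)
class SelectionResult:
    method: str                                   # "SFS" | "SBS"
    selected: Tuple[PairId, ...]
    accuracy: float                               # accuracy of `selected`
    initial_accuracy: float                       # empty set (SFS) / full set (SBS)
    trace: Tuple[Tuple[Tuple[PairId, ...], float], ...]  # chosen-path steps


def _distance_matrix(pair: PairId, payloads_a: List[object],
                     payloads_b: List[object]) -> np.ndarray:
    """Pairwise channel distances, rows = a, columns = b."""
    if pair.rep_type == LAST:
        a = np.asarray(payloads_a, dtype=float)[:, None]
        b = np.asarray(payloads_b, dtype=float)[None, :]
        return np.abs(a - b)
    D = np.empty((len(payloads_a), len(payloads_b)))
    same = payloads_a is payloads_b
    for i, pa in enumerate(payloads_a):
        start = i if same else 0
        for j in range(start, len(payloads_b)):
            D[i, j] = dtw_distance(pa, payloads_b[j])
            if same:
                D[j, i] = D[i, j]
    return D


def _vote_from_row(dist_row: np.ndarray, labels: np.ndarray,
                   exclude: Optional[int], cfg: KnnConfig) -> PairVote:
    # References are index-ordered by encounter id; the stable sort therefore
    # breaks distance ties by encounter id, keeping classification deterministic.
    order = np.argsort(dist_row, kind="stable")
    if exclude is not None:
        order = order[order != exclude]
    if len(order) < cfg.min_neighbors:
        return PairVote(ABSTAIN, None)
    top = order[: cfg.k]
    pos = int(labels[top].sum())
    return _majority(pos, len(top), cfg)


def pair_vote_table(
    pairs: Sequence[PairId],
    payloads: Payloads,
    labels: Mapping[str, bool],
    cfg: KnnConfig,
    leave_one_out: bool = True,
) -> Dict[PairId, Dict[str, PairVote]]:
    """Per-channel KNN vote for every encounter of one labeled part.

    Neighbors are the remaining encounters of the same part (leave-one-out by
    default; with ``leave_one_out=False`` the target itself may be its own
    neighbor, the resubstitution variant).  Encounters lacking a channel's
    representation abstain on it.
    """
    enc_ids = sorted(labels)
    table: Dict[PairId, Dict[str, PairVote]] = {}
    for pair in pairs:
        holders = [e for e in enc_ids if pair in payloads[e]]
        votes: Dict[str, PairVote] = {e: PairVote(ABSTAIN, None) for e in enc_ids}
        if holders:
            pl = [payloads[e][pair] for e in holders]
            lab = np.array([labels[e] for e in holders], dtype=bool)
            D = _distance_matrix(pair, pl, pl)
            for i, e in enumerate(holders):
                votes[e] = _vote_from_row(D[i], lab,
                                          i if leave_one_out else None, cfg)
        table[pair] = votes
    return table


def pair_vote_table_against(
    pairs: Sequence[PairId],
    target_payloads: Payloads,
    ref_payloads: Payloads,
    ref_labels: Mapping[str, bool],
    cfg: KnnConfig,
) -> Dict[PairId, Dict[str, PairVote]]:
    """Per-channel KNN votes for target encounters against a reference part."""
    ref_ids = sorted(ref_labels)
    target_ids = sorted(target_payloads)
    table: Dict[PairId, Dict[str, PairVote]] = {}
    for pair in pairs:
        holders = [e for e in ref_ids if pair in ref_payloads[e]]
        votes: Dict[str, PairVote] = {e: PairVote(ABSTAIN, None) for e in target_ids}
        if holders:
            ref_pl = [ref_payloads[e][pair] for e in holders]
            lab = np.array([ref_labels[e] for e in holders], dtype=bool)
            targets_with = [e for e in target_ids if pair in target_payloads[e]]
            if targets_with:
                tg_pl = [target_payloads[e][pair] for e in targets_with]
                D = _distance_matrix(pair, tg_pl, ref_pl)
                for i, e in enumerate(targets_with):
                    votes[e] = _vote_from_row(D[i], lab, None, cfg)
        table[pair] = votes
    return table


def _positive_matrix(
    pairs: Sequence[PairId],
    votes: Mapping[PairId, Mapping[str, PairVote]],
    enc_ids: Sequence[str],
) -> np.ndarray:
    """Boolean matrix, rows = pairs, columns = encounters: vote == positive."""
    M = np.zeros((len(pairs), len(enc_ids)), dtype=bool)
    for r, pair in enumerate(pairs):
        pv = votes[pair]
        for c, e in enumerate(enc_ids):
            M[r, c] = pv[e].vote == "positive"
    return M


def evaluate_pair_set(
    pair_set: Sequence[PairId],
    votes: Mapping[PairId, Mapping[str, PairVote]],
    labels: Mapping[str, bool],
) -> float:
    """OR-fused classification accuracy of a channel subset.

    The empty set is the all-negative classifier (accuracy 0.5 on balanced
    data); abstains count as negative votes.
    """
    enc_ids = sorted(labels)
    truth = np.array([labels[e] for e in enc_ids], dtype=bool)
    if not pair_set:
        return float((~truth).mean())
    fused = np.zeros(len(enc_ids), dtype=bool)
    for pair in pair_set:
        pv = votes[pair]
        fused |= np.array([pv[e].vote == "positive" for e in enc_ids])
    return float((fused == truth).mean())


def sfs(
    candidates: Sequence[PairId],
    votes: Mapping[PairId, Mapping[str, PairVote]],
    labels: Mapping[str, bool],
) -> SelectionResult:
    """Sequential forward selection under OR-fused accuracy.

    Each iteration adds the candidate maximizing accuracy (ties broken by
    lexicographic PairId via the sorted candidate scan); the loop stops when
    no addition strictly improves accuracy.
    """
    cands = sorted(set(candidates))
    if not cands:
        raise ValueError("need at least one candidate pair")
    enc_ids = sorted(labels)
    truth = np.array([labels[e] for e in enc_ids], dtype=bool)
    pos = _positive_matrix(cands, votes, enc_ids)
    idx = {p: i for i, p in enumerate(cands)}

    selected: List[PairId] = []
    fused = np.zeros(len(enc_ids), dtype=bool)
    best_acc = float((~truth).mean())
    initial = best_acc
    trace: List[Tuple[Tuple[PairId, ...], float]] = []
    remaining = list(cands)
    while remaining:
        step_best, step_pair = -1.0, None
        for p in remaining:  # sorted order => lexicographic tie-break
            acc = float(((fused | pos[idx[p]]) == truth).mean())
            if acc > step_best:
                step_best, step_pair = acc, p
        if step_best <= best_acc:
            break
        selected.append(step_pair)
        fused |= pos[idx[step_pair]]
        best_acc = step_best
        remaining.remove(step_pair)
        trace.append((tuple(selected), best_acc))
    return SelectionResult("SFS", tuple(selected), best_acc, initial, tuple(trace))


def sbs(
    candidates: Sequence[PairId],
    votes: Mapping[PairId, Mapping[str, PairVote]],
    labels: Mapping[str, bool],
) -> SelectionResult:
    """Sequential backward selection under OR-fused accuracy.

    Starting from the full candidate set, each iteration removes the channel
    whose exclusion maximizes accuracy, down to a single channel; the result
    is the best subset seen along the trace (ties prefer the smaller subset,
    then lexicographic order).
    """
    cands = sorted(set(candidates))
    if not cands:
        raise ValueError("need at least one candidate pair")
    enc_ids = sorted(labels)
    truth = np.array([labels[e] for e in enc_ids], dtype=bool)
    pos = _positive_matrix(cands, votes, enc_ids)
    idx = {p: i for i, p in enumerate(cands)}

    def acc_of(subset: Sequence[PairId]) -> float:
        if not subset:
            return float((~truth).mean())
        fused = np.zeros(len(enc_ids), dtype=bool)
        for p in subset:
            fused |= pos[idx[p]]
        return float((fused == truth).mean())

    current = list(cands)
    initial = acc_of(current)
    best_subset, best_acc = tuple(current), initial
    trace: List[Tuple[Tuple[PairId, ...], float]] = []
    while len(current) > 1:
        step_best, step_removed = -1.0, None
        for p in current:  # sorted order => remove lexicographically smallest on ties
            acc = acc_of([q for q in current if q != p])
            if acc > step_best:
                step_best, step_removed = acc, p
        current.remove(step_removed)
        trace.append((tuple(current), step_best))
        better = (step_best > best_acc
                  or (step_best == best_acc and len(current) < len(best_subset)))
        if better:
            best_subset, best_acc = tuple(current), step_best
    return SelectionResult("SBS", best_subset, best_acc, initial, tuple(trace))
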