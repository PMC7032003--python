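"""Shared test utilities: sequence builders and brute-force oracles."""

import numpy as np
import pandas as pd

from akipair import LabSequence

BASE = pd.Timestamp("2010-01-01 00:00")


def seq(points):
    """LabSequence from (hours_from_base, value) pairs."""
    return LabSequence.from_points(
        [(BASE + pd.Timedelta(hours=float(h)), v) for h, v in points]
    )


def dtw_brute_force(s, t):
    """Minimum cumulative |s_i - t_j| over all monotone warping paths.

    Explicit depth-first enumeration of every path from (0,0) to (m-1,n-1)
    with steps right/down/diagonal — independent of the DP recursion.
    """
    m, n = len(s), len(t)
    best = [float("inf")]

    def walk(i, j, acc):
        acc += abs(s[i] - t[j])
        if acc >= best[0]:
            return
        if i == m - 1 and j == n - 1:
            best[0] = acc
            return
        if i + 1 < m and j + 1 < n:
            walk(i + 1, j + 1, acc)
        if i + 1 < m:
            walk(i + 1, j, acc)
        if j + 1 < n:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def qualifying_pairs_brute(sequence, delta=0.3, ratio=1.5, hours=48.0):
    """All (i, j) creatinine pairs within the time window that meet stage 1."""
    t, v = sequence.times, sequence.values
    window = np.timedelta64(int(hours * 60), "m")
    out = []
    for j in range(len(t)):
        for i in range(j):
            if t[j] - t[i] <= window and (
                v[j] - v[i] >= delta - 1e-9 or v[j] / v[i] >= ratio - 1e-9
            ):
                out.append((i, j))
    return out


def auc_brute_force(labels, scores):
    """Pairwise-comparison AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for y, s in zip(labels, scores) if y]
    neg = [s for y, s in zip(labels, scores) if not y]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                wins += 1
            elif p == q:
                wins += 0.5
    return wins / total
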