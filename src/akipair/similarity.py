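"""Similarity measures between two patients for one (laboratory test, type) pair.

Two channels exist per laboratory test: the symbolized last value, compared by
absolute symbol difference (LS), and the symbolized slope sequence, compared by
unnormalized dynamic time warping (TS).  Smaller scores mean more similar
patients; both scores are only ever ranked within a single channel, so they are
kept on their natural scales.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["last_value_similarity", "dtw_distance", "dtw_matrix"]

_VALID_SYMBOLS = frozenset(range(1, 7))


def last_value_similarity(a: int, b: int) -> int:
    """Absolute difference of two 6-level symbols (LS).

    Parameters
    ----------
    a, b : int
        Symbols in {1..6}.

    Returns
    -------
    int
        |a - b|, in {0..5}; 0 means most similar.
    """
    if a not in _VALID_SYMBOLS or b not in _VALID_SYMBOLS:
        raise ValueError(f"symbols must lie in 1..6, got ({a}, {b})")
    return abs(a - b)


def dtw_distance(r1: Sequence[int], r2: Sequence[int]) -> float:
    """Minimum cumulative DTW distance between two symbolic slope sequences.

    Local distance is delta(i, j) = |r1[i] - r2[j]|; the cumulative matrix is
    filled from D(1,1) = delta(1,1) with

        D(i,j) = delta(i,j) + min(D(i,j-1), D(i-1,j-1), D(i-1,j)),

    border cells accumulating along their single available direction.  No
    warping-window constraint and no path-length normalization are applied.

    Raises
    ------
    ValueError
        If either sequence is empty (the trend representation is missing; the
        caller should treat the pair as absent for that patient).
    """
    m, n = len(r1), len(r2)
    if m == 0 or n == 0:
        raise ValueError("DTW requires two non-empty sequences")
    # Rolling single row; python floats beat numpy overhead at these lengths.
    row = [0.0] * n
    acc = 0.0
    r2f = [float(x) for x in r2]
    a = float(r1[0])
    for j in range(n):
        acc += abs(a - r2f[j])
        row[j] = acc
    for i in range(1, m):
        a = float(r1[i])
        prev_diag = row[0]
        row[0] = row[0] + abs(a - r2f[0])
        for j in range(1, n):
            d = abs(a - r2f[j])
            best = row[j]          # D(i-1, j)
            if prev_diag < best:
                best = prev_diag   # D(i-1, j-1)
            if row[j - 1] < best:
                best = row[j - 1]  # D(i, j-1)
            prev_diag = row[j]
            row[j] = d + best
    return row[n - 1]


def dtw_matrix(r1: Sequence[int], r2: Sequence[int]) -> np.ndarray:
    """Full cumulative-distance matrix D (shape m x n) for inspection/tests."""
    m, n = len(r1), len(r2)
    if m == 0 or n == 0:
        raise ValueError("DTW requires two non-empty sequences")
    a = np.asarray(r1, dtype=float)[:, None]
    b = np.asarray(r2, dtype=float)[None, :]
    delta = np.abs(a - b)
    D = np.empty((m, n))
    D[0, :] = np.cumsum(delta[0, :])
    D[:, 0] = np.cumsum(delta[:, 0])
    for i in range(1, m):
        for j in range(1, n):
            D[i, j] = delta[i, j] + min(D[i, j - 1], D[i - 1, j - 1], D[i - 1, j])
    return D
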