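"""Dynamic-time-warping gait-symmetry feature.

A symmetric gait produces nearly identical waveforms for the two feet, so
the minimal-cost DTW alignment between an A-step and the following B-step
has a small total cost; the cost grows as the feet diverge in amplitude or
timing.  The trial-level feature is the mean DTW distance over consecutive
step pairs, which makes it invariant to the arbitrary A/B labelling and
robust to unequal step counts.

The DTW here is the classic unconstrained variant: local cost
``|l_i - r_j|`` (the 1-D Euclidean distance), step set
{(1,0), (0,1), (1,1)}, no warping window.  The dynamic program is compiled
with numba; the recovered path is globally optimal and is verified against
exhaustive path enumeration in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ParameterError
from .segment import CycleSet


@dataclass(frozen=True)
class WarpResult:
    """Optimal warping of two sequences.

    ``distance`` is the minimal cumulative cost; ``path`` the list of
    0-based index pairs from (0, 0) to (n-1, m-1) realising it.
    """

    distance: float
    path: list[tuple[int, int]]
    n: int
    m: int


@njit(cache=False)
def _dtw_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    D = np.empty((n + 1, m + 1))
    D[0, :] = np.inf
    D[:, 0] = np.inf
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            c = abs(ai - b[j - 1])
            d = D[i - 1, j - 1]
            if D[i - 1, j] < d:
                d = D[i - 1, j]
            if D[i, j - 1] < d:
                d = D[i, j - 1]
            D[i, j] = c + d
    return D


@njit(cache=False)
def _dtw_cost_only(a: np.ndarray, b: np.ndarray) -> float:  # pragma: no cover
    """Rolling two-row DP, O(min-memory) distance for long sequences."""
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    prev[:] = np.inf
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[0] = np.inf
        ai = a[i - 1]
        for j in range(1, m + 1):
            c = abs(ai - b[j - 1])
            d = prev[j - 1]
            if prev[j] < d:
                d = prev[j]
            if cur[j - 1] < d:
                d = cur[j - 1]
            cur[j] = c + d
        prev, cur = cur, prev
    return prev[m]


def dtw_distance(left: np.ndarray, right: np.ndarray) -> WarpResult:
    """Globally optimal DTW alignment of two 1-D sequences.

    Returns the minimal total cost and one optimal path.  The distance is
    symmetric in the argument order; identical inputs give distance 0 along
    the diagonal path.
    """
    a = np.ascontiguousarray(left, dtype=float).ravel()
    b = np.ascontiguousarray(right, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ParameterError("dtw_distance requires two non-empty sequences")
    D = _dtw_matrix(a, b)
    # Backtrack one optimal path (ties broken diagonal-first).
    i, j = a.size, b.size
    path = [(i - 1, j - 1)]
    while (i, j) != (1, 1):
        moves = ((D[i - 1, j - 1], i - 1, j - 1), (D[i - 1, j], i - 1, j), (D[i, j - 1], i, j - 1))
        _, i, j = min(moves, key=lambda t: t[0])
        path.append((i - 1, j - 1))
    path.reverse()
    return WarpResult(distance=float(D[a.size, b.size]), path=path, n=a.size, m=b.size)


def symmetry_feature(cycles: CycleSet, mode: str = "pairwise") -> float:
    """Trial-level gait-symmetry score: larger = less symmetric.

    ``pairwise`` (default) averages the DTW distance over all consecutive
    cycle pairs — each pair opposes an A-step and a B-step, so the mean is
    invariant to relabelling A<->B.  ``concat`` warps the concatenated
    A-cycle sequence against the concatenated B-cycle sequence instead.
    """
    if mode not in ("pairwise", "concat"):
        raise ParameterError(f"unknown symmetry mode {mode!r}")
    n_a = len(cycles.by_foot("A"))
    n_b = len(cycles.by_foot("B"))
    if n_a == 0 or n_b == 0:
        raise ParameterError("symmetry_feature needs at least one cycle per foot")
    if mode == "concat":
        a = np.concatenate(cycles.by_foot("A"))
        b = np.concatenate(cycles.by_foot("B"))
        return float(_dtw_cost_only(np.ascontiguousarray(a), np.ascontiguousarray(b)))
    dists = [
        _dtw_cost_only(
            np.ascontiguousarray(cycles.cycles[i], dtype=float),
            np.ascontiguousarray(cycles.cycles[i + 1], dtype=float),
        )
        for i in range(len(cycles) - 1)
    ]
    return float(np.mean(dists))
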