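"""Trajectory similarity: DTW, epsilon-LCSS and a lock-step metric.

DTW accumulates the minimal warp cost D(i, j) = min(D(i-1, j), D(i, j-1),
D(i-1, j-1)) + d(i, j) with D(0, 0) = 0 and an infinite first row/column, so
the distance D(m, n) equals the summed local cost along an optimal
boundary-anchored monotone warp path of length K with max(m, n) <= K < m+n.

LCSS counts order-preserving matches: exact equality when epsilon = 0,
otherwise |a_i - b_j| < epsilon (Euclidean norm for lat/lon pairs). The
normalized distance (m + n - 2z)/(m + n) is 0 for identical sequences and 1
for disjoint ones; the literal (m + n + 2z)/(m + n) variant — which grows
with similarity — is kept behind ``formula="as_printed"`` for fidelity to
how the formula is sometimes printed.

The lock-step metric is the mean point-wise Euclidean distance after
truncating both trajectories to their common length; it stands in for a
third, alignment-free comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .types import SegmentGroup, SimilarityMatrix, Trajectory

logger = logging.getLogger(__name__)

METRICS = ("dtw", "lcss", "lockstep")

#: default LCSS matching tolerances: one quantization unit per representation
DEFAULT_EPSILON = {
    "gps_latlon": 0.001,       # degrees — one rounding cell
    "jerk": 0.1,               # g per second
    "screen_off_bout": 60.0,   # seconds
}


@dataclass
class WarpPath:
    """Monotone index alignment p_1..p_K with 1-based pairs into A and B."""

    pairs: list

    @property
    def K(self) -> int:
        return len(self.pairs)

    def is_valid(self, m: int, n: int) -> bool:
        if not self.pairs or self.pairs[0] != (1, 1) or self.pairs[-1] != (m, n):
            return False
        if not (max(m, n) <= self.K < m + n):
            return False
        for (i0, j0), (i1, j1) in zip(self.pairs, self.pairs[1:]):
            di, dj = i1 - i0, j1 - j0
            if di not in (0, 1) or dj not in (0, 1) or (di == 0 and dj == 0):
                return False
        return True


def _check_pair(A: Trajectory, B: Trajectory, op: str) -> tuple[np.ndarray, np.ndarray]:
    if len(A) == 0 or len(B) == 0:
        raise ValueError(f"{op}: distance undefined for empty trajectories")
    a, b = A.values_2d(), B.values_2d()
    if a.shape[1] != b.shape[1]:
        raise TypeError(f"{op}: trajectories have mixed value kinds")
    return a, b


def dtw_distance(
    A: Trajectory, B: Trajectory, gps_metric: str = "euclidean"
) -> tuple[float, WarpPath]:
    """DTW distance and one optimal warp path (recovered by backtracking).

    The local metric is the Euclidean distance between values — an absolute
    difference for scalar trajectories, planar Euclidean on (lat, lon) degree
    pairs by default, great-circle meters with ``gps_metric="haversine"``.
    """
    a, b = _check_pair(A, B, "dtw_distance")
    if gps_metric == "haversine":
        if a.shape[1] != 2:
            raise TypeError("haversine local metric requires (lat, lon) pairs")
        D = _kernels.dtw_cost_matrix_haversine(a, b)
    elif gps_metric == "euclidean":
        D = _kernels.dtw_cost_matrix(a, b)
    else:
        raise ValueError(f"unknown gps_metric {gps_metric!r}")

    m, n = len(A), len(B)
    # backtrack, preferring the diagonal on ties (keeps the path short)
    pairs = [(m, n)]
    i, j = m, n
    while (i, j) != (1, 1):
        if i == 1:
            j -= 1
        elif j == 1:
            i -= 1
        else:
            diag, up, left = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            if diag <= up and diag <= left:
                i, j = i - 1, j - 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
        pairs.append((i, j))
    pairs.reverse()
    return float(D[m, n]), WarpPath(pairs)


def lcss_length(A: Trajectory, B: Trajectory, epsilon: float) -> int:
    """Length z of the longest common subsequence under tolerance epsilon."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if len(A) == 0 or len(B) == 0:
        return 0
    a, b = A.values_2d(), B.values_2d()
    if a.shape[1] != b.shape[1]:
        raise TypeError("lcss_length: trajectories have mixed value kinds")
    L = _kernels.lcss_table(a, b, float(epsilon))
    return int(L[len(A), len(B)])


def lcss_distance(
    A: Trajectory,
    B: Trajectory,
    epsilon: float,
    formula: str = "normalized",
) -> float:
    """LCSS-based distance; ``normalized`` lies in [0, 1] and is the default."""
    m, n = len(A), len(B)
    if m == 0 and n == 0:
        raise ValueError("lcss_distance undefined for two empty trajectories")
    z = lcss_length(A, B, epsilon)
    if formula == "normalized":
        return (m + n - 2 * z) / (m + n)
    if formula == "as_printed":
        return (m + n + 2 * z) / (m + n)
    raise ValueError(f"unknown formula {formula!r}")


def lockstep_distance(A: Trajectory, B: Trajectory) -> float:
    """Mean point-wise Euclidean distance over the common prefix length."""
    a, b = _check_pair(A, B, "lockstep_distance")
    return float(_kernels.lockstep_mean(a, b))


def _pair_distance(A: Trajectory, B: Trajectory, metric: str, params: dict) -> float:
    if metric == "dtw":
        dist, _ = dtw_distance(A, B, gps_metric=params.get("gps_metric", "euclidean"))
        return dist
    if metric == "lcss":
        eps = params.get("epsilon")
        if eps is None:
            eps = DEFAULT_EPSILON[A.kind.value]
        return lcss_distance(A, B, eps, formula=params.get("formula", "normalized"))
    if metric == "lockstep":
        return lockstep_distance(A, B)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def similarity_matrix(
    group: SegmentGroup, metric: str, params: dict | None = None
) -> SimilarityMatrix:
    """The l x l symmetric pairwise-distance matrix for one group.

    Each distinct pair is computed once and mirrored; the diagonal is zero.
    Pairs whose segments fail the metric's preconditions get NaN (excluded,
    never zero-filled, from all downstream aggregation) with a logged reason.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    params = dict(params or {})
    l = group.size
    if l < 2:
        raise ValueError(f"group {group.key!r} has {l} segment(s); need at least 2")

    values = np.zeros((l, l))
    trajs = group.trajectories()
    ids = group.ids()
    for i in range(l):
        for j in range(i + 1, l):
            try:
                d = _pair_distance(trajs[i], trajs[j], metric, params)
            except (ValueError, TypeError) as exc:
                logger.info(
                    "group %s: pair (%s, %s) missing: %s", group.key, ids[i], ids[j], exc
                )
                d = np.nan
            values[i, j] = values[j, i] = d

    mat = SimilarityMatrix(
        group_key=group.key, metric=metric, values=values, segment_ids=ids, params=params
    )
    mat.validate()
    return mat
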