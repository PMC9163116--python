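"""Hierarchical clustering of segments and barycenter baseline routines.

Clustering runs agglomerative linkage directly on the precomputed trajectory
distance matrix (no feature vectors), so any of the similarity metrics can
drive it. Baselines are DBA-style iterative DTW averages: a representative
trajectory minimising the summed DTW distance to the group's members, which
serves as the personal "typical routine" that individual segments can be
compared against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .similarity import _pair_distance, dtw_distance
from .types import SegmentGroup, SimilarityMatrix, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    segment_ids: list
    linkage_matrix: np.ndarray
    labels: np.ndarray

    def merge_tree(self) -> list:
        """Merge tree as (left, right, height, size) records."""
        return [
            (int(l), int(r), float(h), int(s)) for l, r, h, s in self.linkage_matrix
        ]


@dataclass
class BaselineTrajectory:
    group_key: str
    points: Trajectory
    objective: float
    n_iterations: int
    objective_history: list = field(default_factory=list)


def hierarchical_cluster(
    matrix: SimilarityMatrix, method: str = "average", k: int = 2
) -> ClusterResult:
    """Agglomerative clustering from a precomputed distance matrix.

    Missing entries are imputed at the maximum observed distance (logged):
    incomparable segments should not cluster together. Labels come from
    cutting the merge tree into ``k`` clusters.
    """
    l = matrix.size
    if not 1 <= k <= l:
        raise ValueError(f"k must be in [1, {l}], got {k}")
    values = matrix.values.copy()
    missing = np.isnan(values)
    if missing.any():
        fill = np.nanmax(values) if np.isfinite(np.nanmax(values)) else 1.0
        logger.info(
            "group %s: imputing %d missing pair(s) at max distance %.6g",
            matrix.group_key, int(missing[np.triu_indices(l, 1)].sum()), fill,
        )
        values[missing] = fill
        np.fill_diagonal(values, 0.0)

    Z = linkage(squareform(values, checks=False), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(segment_ids=list(matrix.segment_ids), linkage_matrix=Z, labels=labels)


def _resample(traj: Trajectory, length: int) -> np.ndarray:
    """Linear index-space resampling of the value sequence to ``length``."""
    v = traj.values_2d()
    if len(v) == length:
        return v.copy()
    src = np.linspace(0.0, len(v) - 1, num=length)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, len(v) - 1)
    w = (src - i0)[:, None]
    return (1 - w) * v[i0] + w * v[i1]


def _sum_dtw(center: np.ndarray, members: list[np.ndarray]) -> float:
    from ._kernels import dtw_cost_matrix

    return float(sum(dtw_cost_matrix(mem, center)[len(mem), len(center)] for mem in members))


def dtw_barycenter(
    group: SegmentGroup,
    target_length: int | None = None,
    max_iter: int = 30,
    tol: float = 1e-6,
) -> BaselineTrajectory:
    """DBA-style average trajectory for one group.

    Starts from the group medoid (member with minimal summed DTW distance to
    the others; ties broken by lowest index) resampled to ``target_length``
    (default: the median member length). Each iteration aligns every member
    to the current baseline by DTW and replaces each baseline value with the
    mean of the member values warped onto it; an update that does not lower
    the summed-DTW objective is rejected and iteration stops, so the
    recorded objective history is non-increasing by construction.
    """
    from ._kernels import dtw_cost_matrix

    members = [t for t in group.trajectories() if len(t) >= 2]
    if not members:
        raise ValueError(f"group {group.key!r} has no members with >= 2 points")
    if target_length is None:
        target_length = int(np.median([len(m) for m in members]))
    if target_length < 2:
        raise ValueError("target_length must be at least 2")

    arrays = [m.values_2d() for m in members]

    if len(members) == 1:
        medoid_idx = 0
    else:
        sums = np.zeros(len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                d = dtw_cost_matrix(arrays[i], arrays[j])[len(arrays[i]), len(arrays[j])]
                sums[i] += d
                sums[j] += d
        medoid_idx = int(np.argmin(sums))  # argmin takes the lowest index on ties

    center = _resample(members[medoid_idx], target_length)
    objective = _sum_dtw(center, arrays)
    history = [objective]

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        assoc_sum = np.zeros_like(center)
        assoc_n = np.zeros(len(center))
        for mem in arrays:
            m, n = len(mem), len(center)
            D = dtw_cost_matrix(mem, center)
            i, j = m, n
            while True:
                assoc_sum[j - 1] += mem[i - 1]
                assoc_n[j - 1] += 1
                if (i, j) == (1, 1):
                    break
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
        # every baseline index receives at least one association (path cover)
        candidate = assoc_sum / assoc_n[:, None]
        cand_obj = _sum_dtw(candidate, arrays)
        improvement = objective - cand_obj
        if improvement < 0:  # reject a worsening update, keep monotonicity
            break
        center, objective = candidate, cand_obj
        history.append(objective)
        if improvement < tol:
            break

    ts = np.arange(target_length, dtype=np.int64)
    baseline = Trajectory(ts, center.squeeze(axis=1) if center.shape[1] == 1 else center,
                          members[0].kind)
    return BaselineTrajectory(
        group_key=group.key,
        points=baseline,
        objective=objective,
        n_iterations=n_iter,
        objective_history=history,
    )


def deviation_from_baseline(
    segment: Trajectory,
    baseline: BaselineTrajectory,
    metric: str = "dtw",
    params: dict | None = None,
) -> float:
    """Distance of one segment from its group's baseline routine."""
    if len(segment) == 0 or len(baseline.points) == 0:
        raise ValueError("deviation undefined for empty trajectories")
    if metric == "dtw":
        d, _ = dtw_distance(segment, baseline.points,
                            gps_metric=(params or {}).get("gps_metric", "euclidean"))
        return d
    return _pair_distance(segment, baseline.points, metric, dict(params or {}))
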