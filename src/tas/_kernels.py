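"""Dynamic-programming kernels for DTW and LCSS.

JIT-compiled with numba when available; the pure-Python definitions are the
same code objects, so behaviour is identical either way. Values arrive as
(n, d) float64 arrays with d = 1 (scalar trajectories, where the Euclidean
norm reduces to an absolute difference) or d = 2 (lat/lon pairs).
"""

from __future__ import annotations

import math

import numpy as np


def _dtw_cost_matrix_py(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    m, n = a.shape[0], b.shape[0]
    d = a.shape[1]
    D = np.full((m + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = 0.0
            for c in range(d):
                diff = a[i - 1, c] - b[j - 1, c]
                s += diff * diff
            cost = math.sqrt(s)
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost + best
    return D


def _haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    r = 6_371_000.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    h = math.sin(dp / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2.0) ** 2
    return 2.0 * r * math.asin(min(1.0, math.sqrt(h)))


def _dtw_cost_matrix_haversine_py(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    m, n = a.shape[0], b.shape[0]
    D = np.full((m + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cost = _haversine_m(a[i - 1, 0], a[i - 1, 1], b[j - 1, 0], b[j - 1, 1])
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost + best
    return D


def _lcss_table_py(a: np.ndarray, b: np.ndarray, epsilon: float) -> np.ndarray:
    m, n = a.shape[0], b.shape[0]
    d = a.shape[1]
    L = np.zeros((m + 1, n + 1), dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if epsilon == 0.0:
                match = True
                for c in range(d):
                    if a[i - 1, c] != b[j - 1, c]:
                        match = False
                        break
            else:
                s = 0.0
                for c in range(d):
                    diff = a[i - 1, c] - b[j - 1, c]
                    s += diff * diff
                match = math.sqrt(s) < epsilon
            if match:
                L[i, j] = 1 + L[i - 1, j - 1]
            else:
                up, left = L[i - 1, j], L[i, j - 1]
                L[i, j] = up if up >= left else left
    return L


def _lockstep_py(a: np.ndarray, b: np.ndarray) -> float:
    k = min(a.shape[0], b.shape[0])
    d = a.shape[1]
    total = 0.0
    for i in range(k):
        s = 0.0
        for c in range(d):
            diff = a[i, c] - b[i, c]
            s += diff * diff
        total += math.sqrt(s)
    return total / k


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _haversine_m = njit(cache=True)(_haversine_m)
    dtw_cost_matrix = njit(cache=True)(_dtw_cost_matrix_py)
    dtw_cost_matrix_haversine = njit(cache=True)(_dtw_cost_matrix_haversine_py)
    lcss_table = njit(cache=True)(_lcss_table_py)
    lockstep_mean = njit(cache=True)(_lockstep_py)
except ImportError:  # pragma: no cover
    dtw_cost_matrix = _dtw_cost_matrix_py
    dtw_cost_matrix_haversine = _dtw_cost_matrix_haversine_py
    lcss_table = _lcss_table_py
    lockstep_mean = _lockstep_py
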