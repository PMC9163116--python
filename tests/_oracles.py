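"""Independent reference implementations used only to check the package.

These deliberately share no code with ``tas``: the warp-path oracle
enumerates every monotone boundary-anchored path, the subsequence oracle
recursively enumerates common subsequences, and the reference DTW is a
separate row-by-row dynamic program operating on plain lists.
"""

from __future__ import annotations

import math
from functools import lru_cache


def _local(a, b) -> float:
    if isinstance(a, (tuple, list)):
        return math.dist(a, b)
    return abs(a - b)


def brute_force_dtw(A: list, B: list) -> tuple[float, int, int]:
    """Minimal warp cost by full path enumeration.

    Returns (min cost, shortest optimal path length, longest optimal path
    length) over all monotone paths from (1,1) to (m,n) stepping +0/+1 in
    each index (never both 0).
    """
    m, n = len(A), len(B)
    best = [math.inf]
    lengths = []

    def walk(i: int, j: int, cost: float, length: int) -> None:
        cost += _local(A[i - 1], B[j - 1])
        if cost > best[0]:
            return
        if (i, j) == (m, n):
            if cost < best[0] - 1e-12:
                best[0] = cost
                lengths.clear()
            if abs(cost - best[0]) <= 1e-12:
                lengths.append(length)
            return
        if i < m:
            walk(i + 1, j, cost, length + 1)
        if j < n:
            walk(i, j + 1, cost, length + 1)
        if i < m and j < n:
            walk(i + 1, j + 1, cost, length + 1)

    walk(1, 1, 0.0, 1)
    return best[0], min(lengths), max(lengths)


def reference_dtw(A: list, B: list) -> float:
    """Second, independent DTW dynamic program on plain Python lists."""
    m, n = len(A), len(B)
    prev = [math.inf] * (n + 1)
    prev[0] = 0.0
    for i in range(1, m + 1):
        cur = [math.inf] * (n + 1)
        for j in range(1, n + 1):
            c = _local(A[i - 1], B[j - 1])
            cur[j] = c + min(prev[j], cur[j - 1], prev[j - 1])
        prev = cur
    return prev[n]


def brute_force_lcss(A: tuple, B: tuple, epsilon: float = 0.0) -> int:
    """Longest common subsequence length by exhaustive recursion."""

    def match(a, b) -> bool:
        if epsilon == 0.0:
            return a == b
        return _local(a, b) < epsilon

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == len(A) or j == len(B):
            return 0
        best = max(go(i + 1, j), go(i, j + 1))
        if match(A[i], B[j]):
            best = max(best, 1 + go(i + 1, j + 1))
        return best

    result = go(0, 0)
    go.cache_clear()
    return result


def pearson_closed_form(x: list, y: list) -> float:
    """Pearson r straight from the definition."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den
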