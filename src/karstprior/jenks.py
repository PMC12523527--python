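"""Exact Fisher–Jenks natural-breaks classification in one dimension.

Given n values and k classes, natural breaks chooses the contiguous
partition of the sorted values that minimizes the total within-class sum of
squared deviations (SSD) — the 1-D analogue of minimum-variance clustering,
solved exactly by dynamic programming over prefix sums rather than by
heuristics.

Two implementation choices matter for reproducibility:

* The DP runs over the *unique* sorted values with multiplicities, so equal
  values always land in the same class and classification is a pure
  function of value, never of position among ties.
* Among equal-SSD optima the lexicographically smallest vector of break
  positions is returned (classes fill from the low end first), via a
  suffix-DP reconstruction that always takes the earliest feasible break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class BreaksResult:
    """Optimal contiguous k-partition of a value set.

    ``uppers[i]`` is the largest value of class *i* (ascending); a value v
    belongs to the first class with ``v <= uppers[i]``.  ``ssd`` is the
    minimal total within-class sum of squared deviations.
    """

    k: int
    uppers: tuple[float, ...]
    ssd: float

    def class_of(self, value: float) -> int:
        """0-based class index of *value* (values above the top map to it)."""
        for i, upper in enumerate(self.uppers[:-1]):
            if value <= upper:
                return i
        return self.k - 1


def _prefix_stats(values: np.ndarray, counts: np.ndarray):
    w = np.concatenate([[0.0], np.cumsum(counts)])
    s1 = np.concatenate([[0.0], np.cumsum(counts * values)])
    s2 = np.concatenate([[0.0], np.cumsum(counts * values * values)])

    def ssd(i: int, j: int) -> float:
        # within-class SSD of unique values i..j inclusive
        n = w[j + 1] - w[i]
        lin = s1[j + 1] - s1[i]
        quad = s2[j + 1] - s2[i]
        return max(quad - lin * lin / n, 0.0)

    return ssd


def jenks_breaks(values: Sequence[float], k: int) -> BreaksResult:
    """Exact natural-breaks partition of *values* into *k* classes.

    Raises ``ValueError`` when the number of distinct values is below *k*
    (no contiguous partition can give k non-empty classes of equal values).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot classify an empty value set")
    if k < 1:
        raise ValueError("k must be >= 1")
    uniq, counts = np.unique(arr, return_counts=True)
    m = uniq.size
    if m < k:
        raise ValueError(
            f"need at least k={k} distinct values, got {m}"
        )

    ssd = _prefix_stats(uniq, counts.astype(float))

    # g[i][r]: minimal SSD partitioning unique values i..m-1 into r classes.
    inf = float("inf")
    g = [[inf] * (k + 1) for _ in range(m + 1)]
    g[m][0] = 0.0
    for r in range(1, k + 1):
        # last start index leaving enough values for r classes
        for i in range(m - r, -1, -1):
            best = inf
            # class covers uniq[i..e]; leave >= r-1 values after e
            for e in range(i, m - r + 1):
                tail = g[e + 1][r - 1]
                if tail == inf:
                    continue
                cost = ssd(i, e) + tail
                if cost < best:
                    best = cost
            g[i][r] = best

    # Reconstruct forward, taking the earliest break achieving the optimum:
    # yields the lexicographically smallest break-position vector.
    uppers: list[float] = []
    i, r = 0, k
    while r > 0:
        target = g[i][r]
        for e in range(i, m - r + 1):
            if ssd(i, e) + g[e + 1][r - 1] == target:
                uppers.append(float(uniq[e]))
                i, r = e + 1, r - 1
                break
        else:  # numeric safety net: take the argmin explicitly
            costs = [ssd(i, e) + g[e + 1][r - 1] for e in range(i, m - r + 1)]
            e = i + int(np.argmin(costs))
            uppers.append(float(uniq[e]))
            i, r = e + 1, r - 1

    return BreaksResult(k=k, uppers=tuple(uppers), ssd=float(g[0][k]))
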