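"""One-dimensional class breaks: Fisher-Jenks natural breaks and equal intervals.

Both classifiers produce a :class:`BreakSet` of k+1 ascending edges (min, k-1
interior breaks, max).  Assignment uses half-open intervals [low, high) with
the last class closed, so a value sitting exactly on an interior edge falls in
the upper class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateRangeError, InfeasibleClassificationError, ParameterError

__all__ = ["BreakSet", "jenks_breaks", "equal_interval_breaks", "assign_grades"]


@dataclass
class BreakSet:
    """Class boundaries for a k-class grading scheme."""

    method: str                # "jenks" or "equal_interval"
    k: int
    edges: list[float]         # length k+1, strictly ascending

    def __post_init__(self) -> None:
        if len(self.edges) != self.k + 1:
            raise ParameterError(
                f"need {self.k + 1} edges for k={self.k}, got {len(self.edges)}")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ParameterError(f"edges must be strictly ascending: {self.edges}")

    def to_json(self) -> str:
        return json.dumps({"method": self.method, "k": self.k,
                           "edges": self.edges})

    @classmethod
    def from_json(cls, text: str) -> "BreakSet":
        d = json.loads(text)
        return cls(method=d["method"], k=int(d["k"]),
                   edges=[float(e) for e in d["edges"]])


def _weighted_ssd_prefix(vals: np.ndarray, wts: np.ndarray):
    """Closure computing weighted within-class SSD of vals[i:j] in O(1)."""
    cw = np.concatenate([[0.0], np.cumsum(wts)])
    cs = np.concatenate([[0.0], np.cumsum(wts * vals)])
    cs2 = np.concatenate([[0.0], np.cumsum(wts * vals ** 2)])

    def ssd(i: int, j: int) -> float:  # [i, j) on sorted distinct values
        w = cw[j] - cw[i]
        if w <= 0:
            return 0.0
        s = cs[j] - cs[i]
        return max((cs2[j] - cs2[i]) - s * s / w, 0.0)

    return ssd


def jenks_breaks(values, k: int) -> BreakSet:
    """Optimal k-class natural breaks minimizing within-class sum of squares.

    Dynamic program over the sorted distinct values (duplicates weighted by
    their counts); equal values are never split across classes, which is
    always weakly optimal.  Raises
    :class:`InfeasibleClassificationError` when there are fewer distinct
    values than classes.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0 or np.isnan(arr).any():
        raise ParameterError("values must be non-empty and finite")
    distinct, counts = np.unique(arr, return_counts=True)
    m = len(distinct)
    if m < k:
        raise InfeasibleClassificationError(
            f"{m} distinct values cannot form {k} classes")
    ssd = _weighted_ssd_prefix(distinct, counts.astype(float))

    # cost[c][j]: min SSD of splitting first j distinct values into c classes
    inf = np.inf
    cost = np.full((k + 1, m + 1), inf)
    back = np.zeros((k + 1, m + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, m + 1):
            best, arg = inf, c - 1
            for i in range(c - 1, j):
                cand = cost[c - 1, i] + ssd(i, j)
                if cand < best - 1e-15:
                    best, arg = cand, i
            cost[c, j] = best
            back[c, j] = arg
    # recover split positions (indices into distinct values)
    splits = []
    j = m
    for c in range(k, 0, -1):
        i = back[c, j]
        splits.append(i)
        j = i
    splits = splits[::-1][1:]  # drop the leading 0; k-1 interior positions
    # interior edge between adjacent classes: midpoint of the straddling pair,
    # so edges stay strictly ascending even when a class holds a single value
    edges = [float(distinct[0])]
    edges += [float(0.5 * (distinct[s - 1] + distinct[s])) for s in splits]
    edges.append(float(distinct[-1]))
    return BreakSet(method="jenks", k=k, edges=edges)


def within_class_ssd(values, breaks: BreakSet) -> float:
    """Total within-class sum of squared deviations under a break set."""
    arr = np.asarray(list(values), dtype=float)
    grades = assign_grades(arr, breaks, warn=False)
    total = 0.0
    for g in np.unique(grades):
        sub = arr[grades == g]
        total += float(((sub - sub.mean()) ** 2).sum())
    return total


def equal_interval_breaks(values, k: int) -> BreakSet:
    """Edges at min + j*(max-min)/k for j = 0..k."""
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    arr = np.asarray(list(values), dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if not hi > lo:
        raise DegenerateRangeError(f"degenerate range [{lo}, {hi}]")
    edges = [lo + j * (hi - lo) / k for j in range(k + 1)]
    edges[-1] = hi  # guard against fp drift
    return BreakSet(method="equal_interval", k=k, edges=edges)


def assign_grades(values, breaks: BreakSet, warn: bool = True) -> np.ndarray:
    """Map values to class ids 1..k; out-of-range values clamp to end classes."""
    arr = np.asarray(list(values), dtype=float)
    interior = np.asarray(breaks.edges[1:-1])
    grades = np.searchsorted(interior, arr, side="right") + 1
    out_of_range = (arr < breaks.edges[0]) | (arr > breaks.edges[-1])
    if warn and out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} value(s) outside "
            f"[{breaks.edges[0]}, {breaks.edges[-1]}] clamped to end classes",
            stacklevel=2)
    return grades.astype(int)
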