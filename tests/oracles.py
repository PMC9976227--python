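"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (enumeration / direct formula
evaluation) and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def set_partitions(n: int):
    """All partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, max_label: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    yield from rec(1, 0)


def modularity_direct(w: np.ndarray, labels: np.ndarray) -> float:
    """Q by literal double-sum evaluation on a symmetric weight matrix."""
    two_m = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    for i in range(len(labels)):
        for j in range(len(labels)):
            if labels[i] == labels[j]:
                q += w[i, j] - k[i] * k[j] / two_m
    return q / two_m


def brute_force_best_partition(w: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum-modularity partition by exhaustive enumeration (n <= ~10)."""
    n = w.shape[0]
    two_m = w.sum()
    k = w.sum(axis=1)
    best_q, best = -np.inf, None
    for labels in set_partitions(n):
        q = 0.0
        for c in np.unique(labels):
            mask = labels == c
            q += (w[np.ix_(mask, mask)].sum() / two_m
                  - (k[mask].sum() / two_m) ** 2)
        if q > best_q:
            best_q, best = q, labels
    return best_q, best


def weighted_ssd(values: np.ndarray) -> float:
    if len(values) == 0:
        return 0.0
    return float(((values - values.mean()) ** 2).sum())


def brute_force_jenks_ssd(values, k: int) -> float:
    """Minimal within-class SSD over every split of the sorted values into k
    contiguous classes with ties kept together."""
    arr = np.sort(np.asarray(list(values), dtype=float))
    # split positions are boundaries between distinct values
    distinct = np.unique(arr)
    cuts = [int(np.searchsorted(arr, d)) for d in distinct[1:]]
    best = np.inf
    for combo in itertools.combinations(cuts, k - 1):
        bounds = [0, *combo, len(arr)]
        total = sum(weighted_ssd(arr[a:b]) for a, b in zip(bounds, bounds[1:]))
        best = min(best, total)
    return best


def adjusted_rand(a, b) -> float:
    """Adjusted Rand index between two labelings (contingency-table form)."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    table = np.zeros((len(ua), len(ub)))
    for x, y in zip(ia, ib):
        table[x, y] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(len(a))
    expected = sum_a * sum_b / total
    max_idx = 0.5 * (sum_a + sum_b)
    if max_idx == expected:
        return 1.0
    return float((sum_ij - expected) / (max_idx - expected))
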