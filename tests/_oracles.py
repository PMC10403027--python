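"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and
Lance-Williams implementations: edit distance by plain recursion over the
three elementary operations, LCS by subsequence enumeration, and Ward by
recomputing within-cluster sum-of-squares increases from raw coordinates
at every greedy step.
"""

from functools import lru_cache
from itertools import combinations

import numpy as np


def naive_edit_distance(x, y, sub=2.0, indel=1.0):
    """Minimum edit cost by plain recursion (exponential; lengths <= ~8)."""
    x, y = tuple(x), tuple(y)

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j * indel
        if j == 0:
            return i * indel
        cost = 0.0 if x[i - 1] == y[j - 1] else sub
        return min(
            rec(i - 1, j - 1) + cost,
            rec(i - 1, j) + indel,
            rec(i, j - 1) + indel,
        )

    return rec(len(x), len(y))


def naive_edit_distance_enumerated(x, y, sub=2.0, indel=1.0, _depth=0):
    """Exhaustive enumeration over edit scripts, no memoisation (tiny inputs)."""
    if not x:
        return len(y) * indel
    if not y:
        return len(x) * indel
    subst = (0.0 if x[0] == y[0] else sub) + naive_edit_distance_enumerated(
        x[1:], y[1:], sub, indel
    )
    delete = indel + naive_edit_distance_enumerated(x[1:], y, sub, indel)
    insert = indel + naive_edit_distance_enumerated(x, y[1:], sub, indel)
    return min(subst, delete, insert)


def _is_subsequence(sub, seq):
    it = iter(seq)
    return all(any(s == t for t in it) for s in sub)


def brute_lcs(x, y):
    """Longest common subsequence length by enumerating subsequences of x."""
    x, y = list(x), list(y)
    for length in range(min(len(x), len(y)), 0, -1):
        for idx in combinations(range(len(x)), length):
            if _is_subsequence([x[i] for i in idx], y):
                return length
    return 0


def _ssq(points):
    points = np.asarray(points, dtype=float)
    return float(((points - points.mean(axis=0)) ** 2).sum())


def greedy_ward_oracle(points):
    """Greedy Ward merges recomputed from raw coordinates at every step.

    Returns (merge_partitions, delta_ssqs): at each step the pair of
    current clusters with the smallest increase in within-cluster sum of
    squares is merged (lexicographically smallest pair on ties, clusters
    ordered by their smallest member index).
    """
    points = np.asarray(points, dtype=float)
    clusters = [frozenset([i]) for i in range(len(points))]
    merges, deltas = [], []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            union = clusters[a] | clusters[b]
            delta = (
                _ssq(points[sorted(union)])
                - _ssq(points[sorted(clusters[a])])
                - _ssq(points[sorted(clusters[b])])
            )
            if best is None or delta < best[0] - 1e-12:
                best = (delta, a, b)
        delta, a, b = best
        merges.append((clusters[a], clusters[b]))
        deltas.append(delta)
        union = clusters[a] | clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(union)
        clusters.sort(key=min)
    return merges, deltas


def summary_stats(values):
    """Naive mean/sd/median/iqr recomputation for fixture checks."""
    v = np.sort(np.asarray(values, dtype=float))
    mean = v.sum() / len(v)
    sd = float(np.sqrt(((v - mean) ** 2).sum() / (len(v) - 1))) if len(v) > 1 else 0.0
    return {
        "mean": mean,
        "sd": sd,
        "median": float(np.median(v)),
        "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
    }
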