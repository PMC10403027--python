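"""Optimal-matching and longest-common-subsequence dissimilarities.

Optimal matching (OM) scores the dissimilarity of two state sequences as
the minimum total cost of an edit script — insertions, deletions (jointly
"indels") and substitutions — transforming one into the other.  The
default cost scheme is indel = 1 and a constant substitution cost of 2,
under which OM reduces to the LCS metric:

    d(x, y) = |x| + |y| - 2 * LCS(x, y)

because a substitution (cost 2) never beats deleting one state and
inserting the other (cost 1 + 1).  Distances under the default integer
scheme are exact even integers for equal-length sequences.

The dynamic programs run over the full (|x|+1) x (|y|+1) grid; pairwise
matrices are computed by numba-compiled kernels (pure-Python fallback if
numba is unavailable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .states import N_STATES, SequenceSet, StateSequence, _coerce_states

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


DEFAULT_INDEL = 1.0
DEFAULT_SUBSTITUTION = 2.0


@dataclass(frozen=True)
class CostScheme:
    """Edit-operation costs for optimal matching.

    Attributes
    ----------
    indel : float
        Cost of one insertion or deletion (default 1).
    substitution : (5, 5) ndarray
        Symmetric substitution-cost matrix with zero diagonal; the default
        is a constant 2 off the diagonal.
    """

    indel: float = DEFAULT_INDEL
    substitution: np.ndarray = field(
        default_factory=lambda: constant_substitution(DEFAULT_SUBSTITUTION)
    )

    def __post_init__(self) -> None:
        sub = np.asarray(self.substitution, dtype=float)
        if sub.shape != (N_STATES, N_STATES):
            raise ValueError(f"substitution matrix must be {N_STATES}x{N_STATES}")
        if not np.allclose(sub, sub.T, atol=1e-12):
            raise ValueError("substitution matrix must be symmetric")
        if np.any(np.diag(sub) != 0):
            raise ValueError("substitution matrix must have a zero diagonal")
        if np.any(sub < 0) or self.indel < 0:
            raise ValueError("edit costs must be non-negative")
        sub.flags.writeable = False
        object.__setattr__(self, "substitution", sub)
        object.__setattr__(self, "indel", float(self.indel))


def constant_substitution(cost: float = DEFAULT_SUBSTITUTION) -> np.ndarray:
    """Constant substitution-cost matrix with zero diagonal."""
    sub = np.full((N_STATES, N_STATES), float(cost))
    np.fill_diagonal(sub, 0.0)
    return sub


@njit(cache=False)
def _om_pair(x, y, sub, indel):
    n, m = x.shape[0], y.shape[0]
    prev = np.empty(m + 1, dtype=np.float64)
    cur = np.empty(m + 1, dtype=np.float64)
    for j in range(m + 1):
        prev[j] = j * indel
    for i in range(1, n + 1):
        cur[0] = i * indel
        xi = x[i - 1]
        for j in range(1, m + 1):
            best = prev[j - 1] + sub[xi, y[j - 1]]
            up = prev[j] + indel
            if up < best:
                best = up
            left = cur[j - 1] + indel
            if left < best:
                best = left
            cur[j] = best
        prev, cur = cur, prev
    return prev[m]


@njit(cache=False)
def _lcs_pair(x, y):
    n, m = x.shape[0], y.shape[0]
    prev = np.zeros(m + 1, dtype=np.int64)
    cur = np.zeros(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        cur[0] = 0
        xi = x[i - 1]
        for j in range(1, m + 1):
            if xi == y[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                a = prev[j]
                b = cur[j - 1]
                cur[j] = a if a >= b else b
        prev, cur = cur, prev
    return prev[m]


@njit(cache=False)
def _om_pairwise(data, sub, indel):
    n = data.shape[0]
    out = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            d = _om_pair(data[i], data[j], sub, indel)
            out[i, j] = d
            out[j, i] = d
    return out


def _as_codes(x) -> np.ndarray:
    if isinstance(x, StateSequence):
        return np.asarray(x.states, dtype=np.uint8)
    return _coerce_states(x)


def om_distance(x, y, costs: CostScheme | None = None) -> float:
    """Optimal-matching edit distance between two state sequences.

    Minimum total cost over all scripts of insertions, deletions and
    substitutions transforming ``x`` into ``y``; computed by dynamic
    programming.  Any sequence lengths are accepted.

    Parameters
    ----------
    x, y : StateSequence or sequence of state codes
    costs : CostScheme, optional
        Defaults to indel 1 / constant substitution 2 (the LCS metric).
    """
    costs = costs or CostScheme()
    return float(_om_pair(_as_codes(x), _as_codes(y), costs.substitution, costs.indel))


def lcs_length(x, y) -> int:
    """Length of the longest common subsequence of two sequences."""
    return int(_lcs_pair(_as_codes(x), _as_codes(y)))


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities with their patient ids."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("values must be square and match ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("dissimilarities must be non-negative")
        self.values = v

    def __len__(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


def dissimilarity_matrix(sequences, costs: CostScheme | None = None) -> DissimilarityMatrix:
    """All pairwise OM distances between a set of sequences.

    Only the upper triangle is computed; it is mirrored into a symmetric
    matrix with zero diagonal.

    Parameters
    ----------
    sequences : SequenceSet or iterable of StateSequence
    costs : CostScheme, optional
    """
    if not isinstance(sequences, SequenceSet):
        sequences = list(sequences)
        if sequences and all(isinstance(s, StateSequence) for s in sequences):
            sequences = SequenceSet.from_sequences(sequences)
        else:
            rows = [_as_codes(s) for s in sequences]
            if rows and len({r.size for r in rows}) != 1:
                raise ValueError("sequences must have equal lengths")
            sequences = SequenceSet(
                list(range(len(rows))),
                np.vstack(rows) if rows else np.empty((0, 0), np.uint8),
            )
    if len(sequences) == 0:
        raise ValueError("at least one sequence is required")
    costs = costs or CostScheme()
    values = _om_pairwise(
        np.ascontiguousarray(sequences.data), costs.substitution, costs.indel
    )
    return DissimilarityMatrix(list(sequences.ids), values)


def sample_patients(ids: Sequence, n: int, seed: int) -> list:
    """Simple random sample of ``n`` patient ids without replacement.

    Returns all ids when ``n`` is at least the population size.
    Reproducible for a given seed.
    """
    if n < 0:
        raise ValueError("sample size must be non-negative")
    ids = list(ids)
    if n >= len(ids):
        return ids
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in idx]
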