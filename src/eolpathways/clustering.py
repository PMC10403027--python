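"""Pathway typology: Ward hierarchical classification and its data products.

Hierarchical ascending classification is run directly on the precomputed
OM dissimilarity matrix with Ward's criterion, using the Lance-Williams
recurrence.  The default variant applies the recurrence to *squared*
dissimilarities and reports merge heights on the original scale (the
"ward.D2" convention); the alternative, applying it to the dissimilarities
as given ("ward.D"), is available via ``variant="raw"``.

For Euclidean inputs the squared variant is exactly greedy minimisation of
the within-cluster sum-of-squares increase: the maintained quantity equals
2 x the merge cost Delta-SSQ, which the test suite verifies against a
raw-coordinate oracle.

Merge ties are broken on the lexicographically smallest active index pair,
so the tree is deterministic for a given matrix.  The linkage holds the
full n x n matrix in memory; the reference ceiling is n = 10,000 patients
(the analysis sample size), with tests running at n <= 1,000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import N_STATES, SEQUENCE_LENGTH, CareState, SequenceSet
from .distance import DissimilarityMatrix

#: Descriptive names of the three canonical end-of-life pathway types.
PATHWAY_NAMES = {
    "few_late": "few and late hospitalizations",
    "acute_last3m": "acute care during the last 3 months of life",
    "early_repeated": "early and repeated hospitalizations",
}


@dataclass
class LinkageTree:
    """Agglomerative merge tree in scipy linkage-matrix layout.

    ``merges`` has one row per merge: the two node ids joined (leaves are
    0..n-1, the node created by merge m is n+m), the merge height, and the
    size of the new cluster.
    """

    merges: np.ndarray
    leaf_ids: list

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        self.leaf_ids = list(self.leaf_ids)
        n = len(self.leaf_ids)
        if self.merges.shape != (max(n - 1, 0), 4):
            raise ValueError("a tree over n leaves must have n-1 merges")
        if n > 1 and np.any(self.merges[:, 2] < 0):
            raise ValueError("merge heights must be non-negative")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["node_a", "node_b", "height", "size"]
        ).astype({"node_a": int, "node_b": int, "size": int})


@dataclass
class ClusterTypology:
    """A flat partition of patients into named pathway clusters."""

    k: int
    labels: pd.Series  # patient_id -> cluster id in 1..k
    names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        lab = self.labels.to_numpy()
        if len(lab) == 0:
            raise ValueError("typology must label at least one patient")
        present = np.unique(lab)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError(f"labels must lie in 1..{self.k}")
        if len(present) != self.k:
            raise ValueError("every cluster 1..k must be non-empty")

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def members(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])

    def to_frame(self) -> pd.DataFrame:
        out = self.labels.rename("cluster").rename_axis("patient_id").reset_index()
        if self.names:
            out["name"] = out["cluster"].map(self.names)
        return out


def ward_linkage(D: DissimilarityMatrix, variant: str = "squared") -> LinkageTree:
    """Ward hierarchical ascending classification of a dissimilarity matrix.

    Parameters
    ----------
    D : DissimilarityMatrix
    variant : {"squared", "raw"}
        "squared" (default) applies the Lance-Williams recurrence to squared
        dissimilarities and reports heights on the original scale; "raw"
        applies it to the dissimilarities as given.

    Returns
    -------
    LinkageTree
    """
    if variant not in ("squared", "raw"):
        raise ValueError("variant must be 'squared' or 'raw'")
    n = len(D)
    if n < 2:
        raise ValueError("clustering requires at least 2 observations")

    w = D.values.astype(float) ** 2 if variant == "squared" else D.values.astype(float).copy()
    np.fill_diagonal(w, np.inf)
    sizes = np.ones(n)
    node = np.arange(n)  # current scipy node id of each active row
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4))

    for step in range(n - 1):
        flat = np.argmin(w)  # row-major: lexicographically smallest (i, j)
        i, j = divmod(int(flat), n)
        if i > j:  # pragma: no cover - argmin always finds i < j first
            i, j = j, i
        dij = w[i, j]
        height = np.sqrt(dij) if variant == "squared" else dij

        k = active & (np.arange(n) != i) & (np.arange(n) != j)
        ni, nj, nk = sizes[i], sizes[j], sizes[k]
        w[i, k] = w[k, i] = (
            (ni + nk) * w[i, k] + (nj + nk) * w[j, k] - nk * dij
        ) / (ni + nj + nk)

        merges[step] = (node[i], node[j], height, ni + nj)
        sizes[i] += sizes[j]
        node[i] = n + step
        active[j] = False
        w[j, :] = np.inf
        w[:, j] = np.inf

    return LinkageTree(merges, list(D.ids))


def cut_tree(tree: LinkageTree, k: int) -> ClusterTypology:
    """Partition into ``k`` clusters by undoing the last ``k - 1`` merges.

    Cluster ids 1..k are assigned in order of each cluster's first leaf,
    so the labelling is invariant to input permutations up to that
    canonical renaming.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in 1..{n}")
    parent = np.arange(n + max(n - 1, 0))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for m in range(n - k):
        a, b, _, _ = tree.merges[m]
        new = n + m
        parent[find(int(a))] = new
        parent[find(int(b))] = new

    roots = np.fromiter((find(i) for i in range(n)), dtype=int, count=n)
    labels = np.empty(n, dtype=int)
    mapping: dict[int, int] = {}
    for i, r in enumerate(roots):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    return ClusterTypology(k, pd.Series(labels, index=tree.leaf_ids))


def select_k(
    tree: LinkageTree, k_min: int = 2, k_max: int = 8, default: int | None = None
) -> int:
    """Choose the cluster count at the dendrogram elbow.

    Scores each candidate k by the relative drop between the merge height
    that would destroy the k-cluster partition and the one that created it,
    and returns the k with the largest drop.  Degenerate trees (all heights
    zero) and ties fall back to ``default`` (``k_min`` if unset).
    """
    n = tree.n_leaves
    if not (1 <= k_min <= k_max < n):
        raise ValueError("need 1 <= k_min <= k_max < n")
    if default is None:
        default = k_min
    H = tree.heights
    best_k, best_score, n_best = default, 0.0, 0
    for k in range(max(k_min, 2), k_max + 1):
        above = H[n - k]       # merge reducing k -> k-1 clusters
        below = H[n - k - 1] if n - k - 1 >= 0 else 0.0
        score = 1.0 - below / above if above > 0 else 0.0
        if score > best_score + 1e-12:
            best_k, best_score, n_best = k, score, 1
        elif best_score > 0 and abs(score - best_score) <= 1e-12:
            n_best += 1
    if best_score <= 0 or n_best > 1:
        return default
    return best_k


@dataclass
class Chronogram:
    """Per-cluster daily state-frequency profiles (state distribution plot).

    ``frequencies[c]`` is a (365, 5) matrix: row t holds the distribution
    of the five states among cluster c's members on day t of the window.
    """

    frequencies: dict

    def __post_init__(self) -> None:
        n_days = None
        for c, f in self.frequencies.items():
            f = np.asarray(f, dtype=float)
            if f.ndim != 2 or f.shape[1] != N_STATES:
                raise ValueError("each chronogram must be (n_days, 5)")
            if n_days is None:
                n_days = f.shape[0]
            elif f.shape[0] != n_days:
                raise ValueError("cluster chronograms have unequal day counts")
            if np.any(f < 0) or np.any(np.abs(f.sum(axis=1) - 1) > 1e-9):
                raise ValueError("each day-row must be a probability distribution")
            self.frequencies[c] = f

    def to_frame(self) -> pd.DataFrame:
        """Long format: cluster, day, state, frequency."""
        rows = []
        for c in sorted(self.frequencies):
            f = self.frequencies[c]
            for s in CareState:
                rows.append(
                    pd.DataFrame(
                        {
                            "cluster": c,
                            "day": np.arange(f.shape[0]),
                            "state": s.name,
                            "frequency": f[:, s.value],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def chronogram(sequences: SequenceSet, typology: ClusterTypology) -> Chronogram:
    """State distribution by day within each pathway cluster."""
    labels = typology.labels
    missing = [p for p in sequences.ids if p not in labels.index]
    if missing:
        raise ValueError(f"unlabelled sequences: {missing[:5]}")
    freqs = {}
    lab = labels.loc[sequences.ids].to_numpy()
    for c in range(1, typology.k + 1):
        block = sequences.data[lab == c]
        if block.shape[0] == 0:
            continue
        counts = np.stack(
            [(block == s).sum(axis=0) for s in range(N_STATES)], axis=1
        ).astype(float)
        freqs[c] = counts / block.shape[0]
    return Chronogram(freqs)


def index_plot_order(sequences: SequenceSet, typology: ClusterTypology) -> dict:
    """Within-cluster patient order for rendering sequence index plots.

    Patients are ordered by (first non-HOME day, total non-HOME days,
    patient id); never-hospitalized patients therefore sort last.
    """
    home = CareState.HOME.value
    non_home = sequences.data != home
    first = np.where(
        non_home.any(axis=1), non_home.argmax(axis=1), sequences.n_days
    )
    total = non_home.sum(axis=1)
    keys = {
        p: (int(first[i]), int(total[i]), str(p))
        for i, p in enumerate(sequences.ids)
    }
    out = {}
    for c in range(1, typology.k + 1):
        members = [p for p in sequences.ids if typology.labels.get(p) == c]
        out[c] = sorted(members, key=keys.__getitem__)
    return out


def cluster_profile(
    typology: ClusterTypology, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster descriptive statistics of patient characteristics.

    Returns one row per cluster: n, mean and SD of age at death, percent
    female, mean and SD of the Charlson index.  SD is the sample standard
    deviation, 0 for singleton clusters.
    """
    cohort = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    rows = []
    for c in range(1, typology.k + 1):
        members = typology.members(c)
        if not members:
            warnings.warn(f"cluster {c} is empty; excluded from profile")
            continue
        sub = cohort.loc[members]
        rows.append(
            {
                "cluster": c,
                "name": typology.names.get(c, ""),
                "n": len(sub),
                "age_mean": _mean(sub["age_at_death"]),
                "age_sd": _sd(sub["age_at_death"]),
                "pct_female": 100.0 * (sub["sex"] == "female").mean(),
                "charlson_mean": _mean(sub["charlson_score"]),
                "charlson_sd": _sd(sub["charlson_score"]),
            }
        )
    return pd.DataFrame(rows)


def _mean(x: pd.Series) -> float:
    return float(np.mean(x.to_numpy(dtype=float)))


def _sd(x: pd.Series) -> float:
    v = x.to_numpy(dtype=float)
    return float(np.std(v, ddof=1)) if v.size > 1 else 0.0


def name_clusters(
    chrono: Chronogram,
    hospital_share_low: float = 0.12,
    early_share_high: float = 0.25,
) -> dict:
    """Map clusters to the canonical pathway labels from chronogram shape.

    A cluster with a low overall share of hospital days is "few and late
    hospitalizations"; one whose hospital days concentrate in the last 90
    days is "acute care during the last 3 months of life"; the rest are
    "early and repeated hospitalizations".  Thresholds are the mean share
    of days in hospital states and the share of those days occurring
    before the last 90 days.
    """
    home = CareState.HOME.value
    names = {}
    for c, f in chrono.frequencies.items():
        n_days = f.shape[0]
        hosp = 1.0 - f[:, home]  # expected hospital occupancy per day
        total = hosp.sum()
        share = total / n_days
        early = hosp[: max(n_days - 90, 0)].sum() / total if total > 0 else 0.0
        if share < hospital_share_low:
            names[c] = PATHWAY_NAMES["few_late"]
        elif early < early_share_high:
            names[c] = PATHWAY_NAMES["acute_last3m"]
        else:
            names[c] = PATHWAY_NAMES["early_repeated"]
    return names
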