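"""Ward classification, tree cutting, chronograms and cluster profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

import eolpathways as eol
from eolpathways import (
    ArchetypeConfig,
    CohortConfig,
    DissimilarityMatrix,
    SequenceSet,
    chronogram,
    cluster_profile,
    cut_tree,
    dissimilarity_matrix,
    generate_cohort,
    generate_pathways,
    index_plot_order,
    name_clusters,
    select_k,
    ward_linkage,
)
from eolpathways.clustering import PATHWAY_NAMES, ClusterTypology

from _oracles import greedy_ward_oracle

H = eol.CareState.HOME.value
A = eol.CareState.ACUTE.value
R = eol.CareState.REHAB.value


def euclidean_dissimilarity(points):
    points = np.asarray(points, dtype=float)
    values = squareform(pdist(points))
    return DissimilarityMatrix([f"p{i}" for i in range(len(points))], values)


def merge_partitions(tree):
    """The pair of leaf-sets joined at each merge, for oracle comparison."""
    n = tree.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for m, (a, b, _, _) in enumerate(tree.merges):
        sa, sb = members[int(a)], members[int(b)]
        out.append((sa, sb))
        members[n + m] = sa | sb
    return out


class TestWardLinkage:
    def test_two_leaves_single_merge(self):
        D = euclidean_dissimilarity([[0.0], [3.0]])
        tree = ward_linkage(D)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 3] == 2

    def test_close_pair_merged_first(self):
        # brute-force Ward SSQ: merging {0, 0.1} costs far less than any
        # pair involving the point at 10
        D = euclidean_dissimilarity([[0.0], [0.1], [10.0]])
        tree = ward_linkage(D)
        first = merge_partitions(tree)[0]
        assert first == (frozenset([0]), frozenset([1]))

    def test_matches_exhaustive_ssq_oracle_on_plane(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            points = rng.normal(size=(n, 2))
            tree = ward_linkage(euclidean_dissimilarity(points))
            got = [frozenset([a, b]) for a, b in merge_partitions(tree)]
            oracle_merges, deltas = greedy_ward_oracle(points)
            expected = [frozenset([a, b]) for a, b in oracle_merges]
            assert got == expected
            # heights are sqrt(2 x Delta-SSQ) under the squared variant
            np.testing.assert_allclose(
                tree.heights, np.sqrt(2 * np.asarray(deltas)), atol=1e-9
            )

    def test_matches_scipy_ward_heights(self, rng):
        points = rng.normal(size=(12, 3))
        D = euclidean_dissimilarity(points)
        tree = ward_linkage(D)
        Z = scipy_linkage(D.condensed(), method="ward")
        np.testing.assert_allclose(tree.heights, Z[:, 2], rtol=1e-9)

    def test_heights_monotone(self, rng):
        points = rng.normal(size=(25, 2))
        tree = ward_linkage(euclidean_dissimilarity(points))
        assert (np.diff(tree.heights) >= -1e-9).all()

    def test_permutation_invariance(self, rng):
        points = rng.normal(size=(15, 2))
        D = euclidean_dissimilarity(points)
        perm = rng.permutation(15)
        Dp = DissimilarityMatrix(
            [D.ids[i] for i in perm], D.values[np.ix_(perm, perm)]
        )
        for k in (2, 3, 5):
            part1 = cut_tree(ward_linkage(D), k).labels
            part2 = cut_tree(ward_linkage(Dp), k).labels
            sets1 = {frozenset(part1.index[part1 == c]) for c in range(1, k + 1)}
            sets2 = {frozenset(part2.index[part2 == c]) for c in range(1, k + 1)}
            assert sets1 == sets2

    def test_raw_variant_differs_but_valid(self, rng):
        points = rng.normal(size=(10, 2))
        D = euclidean_dissimilarity(points)
        tree = ward_linkage(D, variant="raw")
        assert (np.diff(tree.heights) >= -1e-9).all()
        with pytest.raises(ValueError):
            ward_linkage(D, variant="other")

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            ward_linkage(DissimilarityMatrix(["a"], np.zeros((1, 1))))


@pytest.fixture(scope="module")
def tree():
    rng = np.random.default_rng(5)
    return ward_linkage(euclidean_dissimilarity(rng.normal(size=(9, 2))))


class TestCutTree:

    def test_k_equals_n_every_leaf_alone(self, tree):
        typ = cut_tree(tree, 9)
        assert sorted(typ.sizes()) == [1] * 9

    def test_k_one_single_cluster(self, tree):
        typ = cut_tree(tree, 1)
        assert typ.sizes().tolist() == [9]

    def test_three_point_toy_partition(self):
        tree = ward_linkage(euclidean_dissimilarity([[0.0], [0.1], [10.0]]))
        typ = cut_tree(tree, 2)
        assert typ.labels["p0"] == typ.labels["p1"] != typ.labels["p2"]

    def test_partitions_at_every_k(self, tree):
        for k in range(1, 10):
            typ = cut_tree(tree, k)
            assert typ.sizes().sum() == 9 and typ.k == k

    def test_out_of_range_k_rejected(self, tree):
        for k in (0, 10):
            with pytest.raises(ValueError):
                cut_tree(tree, k)


class TestSelectK:
    def test_three_noiseless_archetype_groups(self):
        cohort = generate_cohort(CohortConfig(n_patients=30, seed=1))
        seqs, _ = generate_pathways(
            cohort,
            ArchetypeConfig(mixture_weights=(0.5, 0.3, 0.2), per_day_noise=0.0, seed=2),
        )
        tree = ward_linkage(dissimilarity_matrix(seqs))
        assert select_k(tree, 2, 8) == 3

    def test_two_well_separated_blobs(self, rng):
        points = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(20, 0.1, (8, 2))])
        tree = ward_linkage(euclidean_dissimilarity(points))
        assert select_k(tree, 2, 8) == 2

    def test_degenerate_identical_sequences_fall_back_to_default(self):
        values = np.zeros((6, 6))
        tree = ward_linkage(DissimilarityMatrix([f"p{i}" for i in range(6)], values))
        assert select_k(tree, 2, 5) == 2
        assert select_k(tree, 2, 5, default=4) == 4

    def test_bounds_validated(self, rng):
        tree = ward_linkage(euclidean_dissimilarity(rng.normal(size=(5, 2))))
        with pytest.raises(ValueError):
            select_k(tree, 2, 5)  # k_max must stay below n


def _typology(ids, labels, k):
    return ClusterTypology(k, pd.Series(labels, index=ids))


class TestChronogram:
    def test_all_home_cluster_is_home_every_day(self):
        ss = SequenceSet(["a", "b"], np.full((2, 365), H, np.uint8))
        chrono = chronogram(ss, _typology(["a", "b"], [1, 1], 1))
        assert (chrono.frequencies[1][:, H] == 1.0).all()

    def test_rows_sum_to_one(self, rng):
        ss = SequenceSet(list("abcd"), rng.integers(0, 5, (4, 365)).astype(np.uint8))
        chrono = chronogram(ss, _typology(list("abcd"), [1, 1, 2, 2], 2))
        for f in chrono.frequencies.values():
            np.testing.assert_allclose(f.sum(axis=1), 1.0)

    def test_hand_computed_length_five_fixture(self):
        rows = np.array(
            [
                [A, A, H, H, H],
                [A, H, H, R, H],
                [H, H, H, R, H],
            ],
            dtype=np.uint8,
        )
        ss = SequenceSet(["a", "b", "c"], rows)
        chrono = chronogram(ss, _typology(["a", "b", "c"], [1, 1, 1], 1))
        f = chrono.frequencies[1]
        expected_acute = np.array([2 / 3, 1 / 3, 0.0, 0.0, 0.0])
        expected_rehab = np.array([0.0, 0.0, 0.0, 2 / 3, 0.0])
        expected_home = np.array([1 / 3, 2 / 3, 1.0, 1 / 3, 1.0])
        np.testing.assert_allclose(f[:, A], expected_acute)
        np.testing.assert_allclose(f[:, R], expected_rehab)
        np.testing.assert_allclose(f[:, H], expected_home)

    def test_unlabelled_sequence_rejected(self):
        ss = SequenceSet(["a", "b"], np.full((2, 365), H, np.uint8))
        with pytest.raises(ValueError):
            chronogram(ss, _typology(["a"], [1], 1))

    def test_long_format_frame(self):
        ss = SequenceSet(["a"], np.full((1, 365), H, np.uint8))
        frame = chronogram(ss, _typology(["a"], [1], 1)).to_frame()
        assert set(frame.columns) == {"cluster", "day", "state", "frequency"}
        assert len(frame) == 365 * 5


class TestIndexPlotOrder:
    def test_all_home_sorts_after_hospitalized(self):
        data = np.full((2, 365), H, np.uint8)
        data[1, 360] = A
        ss = SequenceSet(["home", "hosp"], data)
        order = index_plot_order(ss, _typology(["home", "hosp"], [1, 1], 1))
        assert order[1] == ["hosp", "home"]

    def test_identical_sequences_tie_break_on_id(self):
        data = np.full((2, 365), H, np.uint8)
        ss = SequenceSet(["z", "a"], data)
        order = index_plot_order(ss, _typology(["z", "a"], [1, 1], 1))
        assert order[1] == ["a", "z"]

    def test_hand_constructed_order(self):
        # p1: first non-home day 10, 5 hospital days
        # p2: first non-home day 10, 2 hospital days  -> before p1
        # p3: first non-home day 3 -> first overall
        # p4: all home -> last
        data = np.full((4, 365), H, np.uint8)
        data[0, 10:15] = A
        data[1, 10:12] = A
        data[2, 3] = R
        ss = SequenceSet(["p1", "p2", "p3", "p4"], data)
        order = index_plot_order(ss, _typology(["p1", "p2", "p3", "p4"], [1] * 4, 1))
        assert order[1] == ["p3", "p2", "p1", "p4"]


@pytest.fixture(scope="module")
def cohort():
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(6)],
            "sex": ["female", "male", "female", "female", "male", "male"],
            "age_at_death": [80.0, 70.0, 90.0, 60.0, 75.0, 85.0],
            "charlson_score": [2, 4, 6, 0, 3, 5],
        }
    )


class TestClusterProfile:
    def test_single_cluster_equals_cohort_summary(self, cohort):
        typ = _typology(cohort["patient_id"], [1] * 6, 1)
        prof = cluster_profile(typ, cohort)
        assert prof.loc[0, "n"] == 6
        np.testing.assert_allclose(prof.loc[0, "age_mean"], 76.666666666667)
        np.testing.assert_allclose(prof.loc[0, "pct_female"], 50.0)

    def test_singleton_cluster_sd_zero(self, cohort):
        typ = _typology(cohort["patient_id"], [1, 1, 1, 1, 1, 2], 2)
        prof = cluster_profile(typ, cohort).set_index("cluster")
        assert prof.loc[2, "age_sd"] == 0.0
        assert prof.loc[2, "age_mean"] == 85.0

    def test_hand_computed_two_cluster_fixture(self, cohort):
        typ = _typology(cohort["patient_id"], [1, 1, 1, 2, 2, 2], 2)
        prof = cluster_profile(typ, cohort).set_index("cluster")
        np.testing.assert_allclose(prof.loc[1, "age_mean"], 80.0)
        np.testing.assert_allclose(prof.loc[1, "age_sd"], 10.0)
        np.testing.assert_allclose(prof.loc[1, "charlson_mean"], 4.0)
        np.testing.assert_allclose(prof.loc[2, "pct_female"], 1 / 3 * 100)


class TestNameClusters:
    def test_archetype_chronograms_get_canonical_names(self):
        cohort = generate_cohort(CohortConfig(n_patients=90, seed=3))
        seqs, truth = generate_pathways(
            cohort,
            ArchetypeConfig(mixture_weights=(1 / 3, 1 / 3, 1 / 3),
                            per_day_noise=0.0, seed=4),
        )
        typ = ClusterTypology(3, pd.Series(truth, index=seqs.ids))
        names = name_clusters(chronogram(seqs, typ))
        assert names[1] == PATHWAY_NAMES["few_late"]
        assert names[2] == PATHWAY_NAMES["acute_last3m"]
        assert names[3] == PATHWAY_NAMES["early_repeated"]
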