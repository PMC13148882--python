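import itertools
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from nullmark.cohort_io import load_reference_panel
from nullmark.genetic_distance import DistanceMatrix, build_matrix
from nullmark.structure_viz import classical_mds, upgma


def matrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"P{i}" for i in range(values.shape[0])]
    return DistanceMatrix(list(labels), values)


def random_metric_matrix(rng, n):
    """Distances among random points in the plane: Euclidean, hence metric."""
    points = rng.random((n, 2))
    return matrix(squareform(pdist(points)))


class TestClassicalMds:
    def test_two_points_embed_at_plus_minus_half(self):
        res = classical_mds(matrix([[0.0, 3.0], [3.0, 0.0]]), k=1)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-1.5, 1.5], abs=1e-12)
        assert res.coordinates.mean(axis=0) == pytest.approx(0.0, abs=1e-12)

    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = classical_mds(matrix(d), k=2)
        recon = squareform(pdist(res.coordinates))
        assert np.allclose(recon[~np.eye(3, dtype=bool)], 1.0, atol=1e-10)

    def test_recovers_euclidean_matrix(self, rng):
        points = rng.random((5, 4))
        d = squareform(pdist(points))
        res = classical_mds(matrix(d), k=4)
        recon = squareform(pdist(res.coordinates))
        assert np.allclose(recon, d, atol=1e-8)
        assert res.reconstruction_error < 1e-8

    def test_centroid_at_origin_and_descending_spectrum(self, rng):
        res = classical_mds(random_metric_matrix(rng, 7), k=3)
        assert np.allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_k_capped_at_positive_eigenvalues(self):
        # 3 collinear points span 1 dimension only.
        d = matrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = classical_mds(d, k=3)
        assert res.k == 1

    def test_sign_convention_deterministic(self, rng):
        m = random_metric_matrix(rng, 6)
        a = classical_mds(m, k=2)
        b = classical_mds(m, k=2)
        assert np.array_equal(a.coordinates, b.coordinates)
        assert (a.coordinates[0] >= -1e-12).all()

    def test_permutation_invariance_of_interpoint_distances(self, rng):
        m = random_metric_matrix(rng, 6)
        perm = rng.permutation(6)
        m_perm = DistanceMatrix(
            [m.labels[i] for i in perm], m.values[np.ix_(perm, perm)]
        )
        d_a = squareform(pdist(classical_mds(m, k=3).coordinates))
        d_b = squareform(pdist(classical_mds(m_perm, k=3).coordinates))
        assert np.allclose(d_b, d_a[np.ix_(perm, perm)], atol=1e-9)

    def test_non_euclidean_input_reports_negative_inertia(self):
        # Violates the triangle inequality strongly -> negative eigenvalues.
        d = matrix([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 3], [1, 1, 3, 0]])
        res = classical_mds(d, k=2)
        assert res.negative_inertia > 0

    def test_infinite_entries_rejected(self):
        d = matrix([[0, math.inf], [math.inf, 0]])
        with pytest.raises(ValueError, match="infinite"):
            classical_mds(d, k=1)


class TestUpgma:
    def test_two_leaves(self):
        tree = upgma(matrix([[0, 4], [4, 0]], labels=["A", "B"]))
        assert tree.merges == [(0, 1, 2.0, 2)]
        assert tree.to_newick() == "(A:2,B:2);"

    def test_hand_worked_four_leaf_example(self):
        # D(A,B)=2, D(C,D)=4, all cross distances 10:
        # merges {A,B}@1, {C,D}@2, root@5.
        d = np.array(
            [
                [0, 2, 10, 10],
                [2, 0, 10, 10],
                [10, 10, 0, 4],
                [10, 10, 4, 0],
            ],
            dtype=float,
        )
        tree = upgma(matrix(d, labels=list("ABCD")))
        heights = [m[2] for m in tree.merges]
        assert heights == pytest.approx([1.0, 2.0, 5.0])
        coph = tree.cophenetic_matrix()
        assert coph[0, 1] == pytest.approx(2.0)
        assert coph[2, 3] == pytest.approx(4.0)
        assert coph[0, 2] == pytest.approx(10.0)

    def test_cophenetic_matches_scipy_oracle(self, rng):
        for _ in range(20):
            d = squareform(pdist(rng.random((6, 3))))
            tree = upgma(matrix(d))
            z = linkage(squareform(d), method="average")
            expected = squareform(cophenet(z))
            assert np.allclose(tree.cophenetic_matrix(), expected, atol=1e-10)

    def test_ultrametric_on_random_matrices(self, rng):
        """max-of-path test: for any leaf triple the two largest cophenetic
        distances are equal, and merge heights never decrease."""
        for _ in range(100):
            n = int(rng.integers(3, 8))
            d = squareform(pdist(rng.random((n, 2))))
            tree = upgma(matrix(d))
            heights = [m[2] for m in tree.merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))
            coph = tree.cophenetic_matrix()
            for i, j, k in itertools.combinations(range(n), 3):
                trio = sorted([coph[i, j], coph[i, k], coph[j, k]])
                assert trio[1] == pytest.approx(trio[2], abs=1e-10)

    def test_relabeling_invariance(self, rng):
        d = squareform(pdist(rng.random((5, 2))))
        m = matrix(d, labels=list("ABCDE"))
        perm = [3, 1, 4, 0, 2]
        m_perm = DistanceMatrix([m.labels[i] for i in perm], d[np.ix_(perm, perm)])
        coph_a = upgma(m).cophenetic_matrix()
        coph_b = upgma(m_perm).cophenetic_matrix()
        assert np.allclose(coph_b, coph_a[np.ix_(perm, perm)], atol=1e-10)

    def test_tie_break_is_lexicographic(self):
        # Two equally-close pairs; the (A,B) merge must come first.
        d = np.array(
            [
                [0, 1, 5, 5],
                [1, 0, 5, 5],
                [5, 5, 0, 1],
                [5, 5, 1, 0],
            ],
            dtype=float,
        )
        tree = upgma(matrix(d, labels=["Z", "A", "B", "Y"]))
        first_left, first_right, _, _ = tree.merges[0]
        assert {tree.labels[first_left], tree.labels[first_right]} == {"A", "Z"}

    def test_newick_branch_lengths_are_height_differences(self):
        d = np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float)
        tree = upgma(matrix(d, labels=["A", "B", "C"]))
        assert tree.to_newick() == "((A:1,B:1):3,C:4);"

    def test_infinite_entries_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            upgma(matrix([[0, math.inf], [math.inf, 0]]))


def test_nearest_neighbor_on_reference_panel_is_portugal():
    """At the GSTM1 locus the study cohort's nearest reference is Portugal."""
    panel = load_reference_panel().subset(
        [
            "Current study (Venezuela)",
            "Portuguese",
            "Ibo (Abuja)",
            "Yoruba (Abuja)",
            "Mexico (central)",
            "Chinese (Beijing)",
            "Japanese (Tokyo)",
            "Wayuu (ethnic group, Venezuela)",
            "Spanish (Madrid)",
            "Italian (Rome)",
        ]
    )
    m = build_matrix(panel, loci=["GSTM1"])
    i = m.labels.index("Current study (Venezuela)")
    distances = {lab: m.values[i, j] for j, lab in enumerate(m.labels) if j != i}
    assert min(distances, key=distances.get) == "Portuguese"
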