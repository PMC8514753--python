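"""GIP kernel, normalizations, neighborhoods and kernel fusion."""

import numpy as np
import pytest

from conftest import make_association, make_kernel

from ilpmda import (
    AlignmentError,
    AssociationMatrix,
    DegenerateBandwidthError,
    FusionParams,
    NormalizationError,
    SimilarityKernel,
    ValidationError,
    average_fuse,
    gip_bandwidth,
    gip_kernel,
    mutual_neighbor_weights,
    neighbor_constraint_kernel,
    neighbor_sets,
    normalize_kernel,
    skf_fuse,
)


class TestGipKernel:
    def test_two_by_two_identity_toy(self):
        """A = I2 with rho' = 1: mean squared profile norm is 1, so the
        off-diagonal is exp(-1 * ||(1,0)-(0,1)||^2) = exp(-2)."""
        A = AssociationMatrix(np.eye(2), ["d1", "d2"], ["m1", "m2"])
        assert gip_bandwidth(A, "disease") == pytest.approx(1.0, abs=0)
        K = gip_kernel(A, "disease")
        assert K.values[0, 0] == 1.0 and K.values[1, 1] == 1.0
        assert K.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)
        assert K.values[1, 0] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_identical_profiles_have_similarity_one(self):
        A = AssociationMatrix(
            [[1, 0, 1], [1, 0, 1]], ["d1", "d2"], ["m1", "m2", "m3"]
        )
        K = gip_kernel(A, "disease")
        assert K.values[0, 1] == pytest.approx(1.0, abs=1e-15)

    def test_symmetry_unit_diagonal_and_range(self, rng):
        for _ in range(20):
            A = make_association(rng, int(rng.integers(2, 10)), int(rng.integers(2, 10)))
            for side in ("disease", "mirna"):
                K = gip_kernel(A, side)
                assert np.array_equal(K.values, K.values.T)
                assert np.all(np.diag(K.values) == 1.0)
                assert np.all(K.values > 0.0) and np.all(K.values <= 1.0)

    def test_duplicating_mirna_columns_leaves_disease_kernel_unchanged(self, rng):
        """Doubling every column doubles both the squared distances and the
        mean squared norm, so the effective bandwidth halves and the
        disease kernel is algebraically unchanged."""
        A = make_association(rng, 6, 5)
        doubled = AssociationMatrix(
            np.hstack([A.values, A.values]),
            A.disease_labels,
            A.mirna_labels + [f"{m}_copy" for m in A.mirna_labels],
        )
        K1 = gip_kernel(A, "disease")
        K2 = gip_kernel(doubled, "disease")
        assert gip_bandwidth(doubled, "disease") == pytest.approx(
            gip_bandwidth(A, "disease") / 2.0, rel=1e-12
        )
        np.testing.assert_allclose(K1.values, K2.values, atol=1e-12)

    def test_relabeling_permutation_equivariance(self, rng):
        A = make_association(rng, 7, 5)
        perm = rng.permutation(7)
        permuted = AssociationMatrix(
            A.values[perm], [A.disease_labels[i] for i in perm], A.mirna_labels
        )
        K = gip_kernel(A, "disease")
        Kp = gip_kernel(permuted, "disease")
        np.testing.assert_allclose(Kp.values, K.values[np.ix_(perm, perm)], atol=1e-12)

    def test_all_zero_matrix_raises_degenerate_bandwidth(self):
        A = AssociationMatrix(np.zeros((3, 4)), ["a", "b", "c"], list("wxyz"))
        with pytest.raises(DegenerateBandwidthError):
            gip_kernel(A, "disease")


class TestNormalizeKernel:
    def test_identity_is_fixed_point(self):
        K = SimilarityKernel(np.eye(2), ["a", "b"], "disease")
        P = normalize_kernel(K)
        assert np.array_equal(P.values, np.eye(2))
        assert P.orientation == "column"

    def test_constant_kernel_becomes_uniform(self):
        K = SimilarityKernel(np.ones((3, 3)), ["a", "b", "c"], "disease")
        assert np.allclose(normalize_kernel(K).values, 1.0 / 3.0)

    def test_columns_sum_to_one(self, rng):
        for _ in range(20):
            K = make_kernel(rng, 5)
            P = normalize_kernel(K)
            np.testing.assert_allclose(P.values.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_column_names_the_entity(self):
        vals = np.array([[1.0, 0.0], [0.0, 0.0]])
        K = SimilarityKernel(vals, ["good", "isolated"], "disease")
        with pytest.raises(NormalizationError, match="isolated"):
            normalize_kernel(K)


THREE_NODE = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]])


class TestNeighborSets:
    def test_three_node_example(self):
        K = SimilarityKernel(THREE_NODE, ["d1", "d2", "d3"], "disease")
        nbrs = neighbor_sets(K, k=2, include_self=True)
        assert nbrs.neighbors[0] == [0, 1]  # self + most similar other
        assert nbrs.neighbors[1] == [1, 0]
        assert nbrs.neighbors[2] == [2, 1]

    def test_k_equals_n_selects_everyone(self, rng):
        K = make_kernel(rng, 5)
        nbrs = neighbor_sets(K, k=5, include_self=True)
        for nb in nbrs.neighbors:
            assert sorted(nb) == list(range(5))

    def test_tie_broken_by_lower_index(self):
        vals = np.full((3, 3), 0.5)
        np.fill_diagonal(vals, 1.0)
        K = SimilarityKernel(vals, ["a", "b", "c"], "disease")
        nbrs = neighbor_sets(K, k=2, include_self=True)
        assert nbrs.neighbors[2] == [2, 0]  # b and a tie at 0.5 -> index 0 wins

    def test_oversized_k_clipped_with_warning(self, rng):
        K = make_kernel(rng, 4)
        with pytest.warns(UserWarning, match="clipping"):
            nbrs = neighbor_sets(K, k=10, include_self=False)
        assert all(len(nb) == 3 for nb in nbrs.neighbors)

    def test_matches_brute_force_sort(self, rng):
        for _ in range(10):
            K = make_kernel(rng, 8)
            k = int(rng.integers(1, 8))
            nbrs = neighbor_sets(K, k, include_self=False)
            for i in range(8):
                expected = sorted(
                    (j for j in range(8) if j != i),
                    key=lambda j: (-K.values[i, j], j),
                )[:k]
                assert nbrs.neighbors[i] == expected


class TestNeighborConstraintKernel:
    def test_three_node_hand_evaluation(self):
        K = SimilarityKernel(THREE_NODE, ["d1", "d2", "d3"], "disease")
        C = neighbor_constraint_kernel(K, neighbor_sets(K, 2, include_self=True))
        np.testing.assert_allclose(C.values[0], [1 / 1.9, 0.9 / 1.9, 0.0], atol=1e-12)

    def test_full_neighborhood_is_row_normalization(self, rng):
        K = make_kernel(rng, 6)
        C = neighbor_constraint_kernel(K, neighbor_sets(K, 6, include_self=True))
        np.testing.assert_allclose(
            C.values, K.values / K.values.sum(axis=1, keepdims=True), atol=1e-12
        )

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            K = make_kernel(rng, 7)
            k = int(rng.integers(1, 8))
            C = neighbor_constraint_kernel(K, neighbor_sets(K, k, include_self=True))
            np.testing.assert_allclose(C.values.sum(axis=1), 1.0, atol=1e-12)


class TestMutualNeighborWeights:
    def test_diagonal_is_one_with_self_included(self, rng):
        K = make_kernel(rng, 6)
        W = mutual_neighbor_weights(neighbor_sets(K, 3, include_self=True), 6)
        assert np.all(np.diag(W.values) == 1.0)

    def test_matches_brute_force_membership(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 10))
            K = make_kernel(rng, n)
            k = int(rng.integers(1, n + 1))
            nbrs = neighbor_sets(K, k, include_self=True)
            W = mutual_neighbor_weights(nbrs, n)
            sets = [set(nb) for nb in nbrs.neighbors]
            for i in range(n):
                for j in range(n):
                    in_ij = j in sets[i]
                    in_ji = i in sets[j]
                    expected = 1.0 if (in_ij and in_ji) else 0.0 if not (in_ij or in_ji) else 0.5
                    assert W.values[i, j] == expected


class TestSkfFuse:
    def test_identical_kernels_stay_exchangeable(self, rng):
        """With two identical inputs the cross term for each kernel is the
        other (identical) kernel, so both iterate sequences coincide and
        the fusion converges."""
        K = make_kernel(rng, 6)
        K2 = SimilarityKernel(K.values.copy(), K.labels, K.side)
        params = FusionParams(k_neighbors=4)
        r1 = skf_fuse([K, K2], params)
        r2 = skf_fuse([K2, K], params)
        assert r1.converged
        np.testing.assert_array_equal(r1.kernel.values, r2.kernel.values)

    def test_output_symmetric_nonnegative(self, rng):
        kernels = [make_kernel(rng, 8) for _ in range(3)]
        result = skf_fuse(kernels, FusionParams(k_neighbors=4))
        V = result.kernel.values
        assert np.array_equal(V, V.T)
        assert V.min() >= 0.0

    def test_invariant_to_kernel_list_order(self, rng):
        kernels = [make_kernel(rng, 7) for _ in range(3)]
        params = FusionParams(k_neighbors=5)
        a = skf_fuse(kernels, params).kernel.values
        b = skf_fuse([kernels[2], kernels[0], kernels[1]], params).kernel.values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_single_kernel_degenerates_to_normalization(self, rng):
        K = make_kernel(rng, 5)
        result = skf_fuse([K], FusionParams(k_neighbors=3))
        P = normalize_kernel(K).values
        np.testing.assert_allclose(result.kernel.values, (P + P.T) / 2.0, atol=1e-15)
        assert result.iterations == 0 and result.converged

    def test_label_mismatch_rejected(self, rng):
        K1 = make_kernel(rng, 4)
        K2 = make_kernel(rng, 4, labels=["w", "x", "y", "z"])
        with pytest.raises(AlignmentError):
            skf_fuse([K1, K2], FusionParams())


class TestAverageFuse:
    def test_mean_of_identical_kernels_is_that_kernel(self, rng):
        K = make_kernel(rng, 5)
        fused = average_fuse([K, K, K])
        np.testing.assert_allclose(fused.values, K.values, atol=1e-15)

    def test_mean_with_zero_matrix_halves(self, rng):
        K = make_kernel(rng, 4)
        zero = SimilarityKernel(np.zeros((4, 4)), K.labels, K.side)
        np.testing.assert_allclose(average_fuse([K, zero]).values, K.values / 2.0, atol=1e-15)

    def test_matches_elementwise_mean_oracle(self, rng):
        kernels = [make_kernel(rng, 6) for _ in range(3)]
        expected = (kernels[0].values + kernels[1].values + kernels[2].values) / 3.0
        np.testing.assert_allclose(average_fuse(kernels).values, expected, atol=1e-15)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            average_fuse([])
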