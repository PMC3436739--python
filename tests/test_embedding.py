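"""Dissimilarity transform, classical MDS, P_k, and the permutation null."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from coevo3d.embedding import (
    DissimilarityMatrix,
    classical_mds,
    goodness_of_fit,
    permutation_null,
    to_dissimilarity,
)
from coevo3d.mirror_tree import CoevolutionMatrix


def _coevo(rho, ids=None):
    rho = np.asarray(rho, dtype=float)
    n = rho.shape[0]
    ids = ids or [f"u{i}" for i in range(n)]
    return CoevolutionMatrix(ids, rho, np.full((n, n), 10))


def _euclidean_D(points, ids=None):
    points = np.asarray(points, dtype=float)
    d = squareform(pdist(points))
    mx = d.max()
    return DissimilarityMatrix(
        ids or [f"u{i}" for i in range(len(points))], d / mx
    ), mx


def _random_points(n, dim, seed):
    return np.random.default_rng(seed).uniform(-1, 1, size=(n, dim))


class TestToDissimilarity:
    def test_perfect_correlation_gives_zero_distance(self):
        R = _coevo(np.ones((4, 4)))
        D = to_dissimilarity(R)
        assert np.allclose(D.d, 0.0)

    def test_arithmetic_example(self):
        rho = np.array(
            [[1.0, 0.5, -0.5], [0.5, 1.0, 0.5], [-0.5, 0.5, 1.0]]
        )
        D = to_dissimilarity(_coevo(rho))
        # d' = {0.5, 1.5}; max = 1.5 -> d = {1/3, 1}
        assert D.d[0, 1] == pytest.approx(1 / 3)
        assert D.d[0, 2] == pytest.approx(1.0)
        assert np.allclose(np.diag(D.d), 0.0)
        assert D.d.max() == pytest.approx(1.0)

    def test_undefined_cell_error_names_the_pair(self):
        rho = np.ones((3, 3))
        rho[0, 2] = rho[2, 0] = np.nan
        with pytest.raises(ValueError, match=r"\(a, c\)"):
            to_dissimilarity(_coevo(rho, ids=["a", "b", "c"]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rescale_removes_any_positive_prefactor(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        r = rng.uniform(-0.9, 0.9, size=(n, n))
        rho = (r + r.T) / 2
        np.fill_diagonal(rho, 1.0)
        D1 = to_dissimilarity(_coevo(rho)).d
        # shrinking all correlations toward 1 scales d' by c; d is unchanged
        c = 0.25
        rho2 = 1.0 - c * (1.0 - rho)
        np.fill_diagonal(rho2, 1.0)
        D2 = to_dissimilarity(_coevo(rho2)).d
        np.testing.assert_allclose(D1, D2, atol=1e-10)


class TestClassicalMDS:
    def test_exact_euclidean_input_is_reproduced(self):
        D, scale = _euclidean_D(_random_points(4, 3, seed=0))
        emb = classical_mds(D, k=3)
        np.testing.assert_allclose(emb.embedded_distances(), D.d, atol=1e-9)
        assert emb.p_k == pytest.approx(1.0, abs=1e-9)

    def test_equilateral_triangle_spectrum(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        D, _ = _euclidean_D(pts)
        emb = classical_mds(D, k=2)
        w = emb.eigenvalues
        assert w[0] == pytest.approx(w[1], rel=1e-9)
        assert abs(w[2]) < 1e-9 * w[0]

    def test_five_dimensional_input_full_and_truncated(self):
        pts = _random_points(10, 5, seed=1)
        D, scale = _euclidean_D(pts)
        emb5 = classical_mds(D, k=5)
        np.testing.assert_allclose(emb5.embedded_distances(), D.d, atol=1e-9)
        # truncation to k=3 equals the top-3 principal-axis projection
        emb3 = classical_mds(D, k=3)
        centered = pts / scale - (pts / scale).mean(axis=0)
        _, s, Vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ Vt[:3].T
        np.testing.assert_allclose(
            emb3.embedded_distances(), squareform(pdist(proj)), atol=1e-9
        )

    def test_structural_invariants(self):
        """Double-centering, trace conservation, column norms, centering."""
        from coevo3d.embedding import _double_center

        rng = np.random.default_rng(2)
        d = np.abs(rng.uniform(0.1, 1.0, size=(8, 8)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        D = DissimilarityMatrix([f"u{i}" for i in range(8)], d / d.max())
        B = _double_center(D.d)
        assert np.abs(B.sum(axis=0)).max() < 1e-8
        assert np.abs(B.sum(axis=1)).max() < 1e-8
        emb = classical_mds(D, k=3)
        assert emb.eigenvalues.sum() == pytest.approx(np.trace(B), abs=1e-8)
        assert np.abs(emb.coordinates.mean(axis=0)).max() < 1e-9
        for j in range(3):
            lam = emb.eigenvalues[j]
            if lam > 0:
                assert np.sum(emb.coordinates[:, j] ** 2) == pytest.approx(
                    lam, rel=1e-8
                )
        assert np.all(np.diff(emb.eigenvalues) <= 1e-12)

    def test_matches_scikit_bio_pcoa(self):
        """Independent cross-check of the eigendecomposition route."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa

        D, _ = _euclidean_D(_random_points(9, 4, seed=3))
        emb = classical_mds(D, k=3)
        ord_res = pcoa(skbio.DistanceMatrix(D.d, ids=D.unit_ids), method="eigh")
        np.testing.assert_allclose(
            emb.eigenvalues[:3],
            ord_res.eigvals.to_numpy()[:3],
            rtol=1e-8,
            atol=1e-10,
        )
        np.testing.assert_allclose(
            np.abs(emb.coordinates[:, :3]),
            np.abs(ord_res.samples.to_numpy()[:, :3]),
            atol=1e-6,
        )

    def test_deficient_rank_warns_and_zero_fills(self):
        pts = np.zeros((5, 3))
        pts[:, 0] = np.arange(5.0)  # collinear -> 1 positive eigenvalue
        D, _ = _euclidean_D(pts)
        with pytest.warns(UserWarning, match="positive eigenvalue"):
            emb = classical_mds(D, k=3)
        assert np.allclose(emb.coordinates[:, 1:], 0.0)

    def test_asymmetric_input_is_an_error(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(["a", "b", "c"], d)

    def test_too_few_units_is_an_error(self):
        D, _ = _euclidean_D(_random_points(3, 2, seed=4))
        with pytest.raises(ValueError, match="k\\+1"):
            classical_mds(D, k=3)


class TestGoodnessOfFit:
    def test_arithmetic_example_positive_policy(self):
        w = np.array([4.0, 2.0, 1.0, 1.0, 0.0, 0.0])
        assert goodness_of_fit(w, 3) == pytest.approx(7 / 8)

    def test_policies_differ_on_negative_eigenvalues(self):
        w = np.array([4.0, 2.0, 1.0, 0.0, -1.0])
        assert goodness_of_fit(w, 3, "positive") == pytest.approx(1.0)
        assert goodness_of_fit(w, 3, "absolute") == pytest.approx(7 / 8)
        assert goodness_of_fit(w, 3, "raw") == pytest.approx(7 / 7)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(5)
        d = np.abs(rng.normal(size=(10, 10)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        D = DissimilarityMatrix([f"u{i}" for i in range(10)], d / d.max())
        w = classical_mds(D, k=3).eigenvalues
        vals = [goodness_of_fit(w, k) for k in range(1, 10)]
        assert np.all(np.diff(vals) >= -1e-12)

    @pytest.mark.parametrize("c", [0.1, 10.0])
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(6)
        d = np.abs(rng.normal(size=(8, 8)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"u{i}" for i in range(8)]
        D1 = DissimilarityMatrix(ids, d / d.max())
        D2 = DissimilarityMatrix(ids, c * d / d.max())
        # bypass the [0,1] construction check for c=10 by scaling eigenvalues
        w1 = classical_mds(D1, k=3).eigenvalues
        w2 = w1 * c**2
        assert goodness_of_fit(w1, 3) == pytest.approx(
            goodness_of_fit(w2, 3), abs=1e-12
        )


class TestPermutationNull:
    def test_reproducible_with_same_seed(self):
        D, _ = _euclidean_D(_random_points(8, 3, seed=7))
        a = permutation_null(D, n_perm=100, seed=42)
        b = permutation_null(D, n_perm=100, seed=42)
        np.testing.assert_array_equal(a.null_p_k, b.null_p_k)
        assert a.p_value == b.p_value

    def test_structured_matrix_beats_null(self):
        D, _ = _euclidean_D(_random_points(12, 3, seed=8))
        null = permutation_null(D, n_perm=200, seed=0)
        assert null.observed == pytest.approx(1.0, abs=1e-9)
        assert null.p_value <= 1 / (1 + 200) + 1e-12

    def test_random_matrix_is_calibrated(self):
        """An i.i.d. matrix's P_3 falls inside the null central 99% interval."""
        rng = np.random.default_rng(9)
        d = rng.uniform(0.05, 1.0, size=(10, 10))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        D = DissimilarityMatrix([f"u{i}" for i in range(10)], d / d.max())
        null = permutation_null(D, n_perm=1000, seed=1)
        lo, hi = np.quantile(null.null_p_k, [0.005, 0.995])
        assert lo <= null.observed <= hi

    def test_small_matrix_is_an_error(self):
        D, _ = _euclidean_D(_random_points(3, 2, seed=10))
        with pytest.raises(ValueError, match="n >= 4"):
            permutation_null(D, n_perm=100, seed=0, k=2)

    def test_too_few_permutations_is_an_error(self):
        D, _ = _euclidean_D(_random_points(6, 3, seed=11))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(D, n_perm=10, seed=0)
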