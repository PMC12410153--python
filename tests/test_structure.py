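import numpy as np
import pytest

from socialconcord import (
    FeatureCorrelationMatrix,
    MeanRatingMatrix,
    feature_correlation_matrix,
    loading_concordance,
    mantel_test,
    matrix_similarity,
    pcoa,
)

from oracles import (
    brute_matrix_similarity,
    brute_pcoa_distances,
    brute_pearson,
    exhaustive_mantel_p,
)


def _mean_matrix(values):
    values = np.asarray(values, float)
    return MeanRatingMatrix(
        items=[f"i{k}" for k in range(values.shape[0])],
        features=[f"f{k}" for k in range(values.shape[1])],
        values=values,
        n_contributing=np.ones(values.shape, int),
    )


def _random_corr(rng, f):
    x = rng.standard_normal((f + 5, f))
    return FeatureCorrelationMatrix([f"f{k}" for k in range(f)],
                                    np.corrcoef(x, rowvar=False))


class TestFeatureCorrelationMatrix:
    def test_identical_and_negated_columns(self, rng):
        base = rng.uniform(0, 10, 8)
        mat = _mean_matrix(np.column_stack([base, base, 10 - base]))
        corr = feature_correlation_matrix(mat)
        assert corr.values[0, 1] == pytest.approx(1.0)
        assert corr.values[0, 2] == pytest.approx(-1.0)

    def test_matches_pairwise_brute_force(self, rng):
        vals = rng.uniform(0, 10, size=(7, 4))
        corr = feature_correlation_matrix(_mean_matrix(vals))
        for i in range(4):
            for j in range(4):
                expected = 1.0 if i == j else brute_pearson(vals[:, i], vals[:, j])
                assert corr.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_feature_is_integrity_error(self, rng):
        vals = rng.uniform(0, 10, size=(6, 3))
        vals[:, 1] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            feature_correlation_matrix(_mean_matrix(vals))


class TestMatrixSimilarity:
    def test_self_similarity_is_one(self, rng):
        a = _random_corr(rng, 5)
        assert matrix_similarity(a, a) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        a, b = _random_corr(rng, 6), _random_corr(rng, 6)
        assert matrix_similarity(a, b) == pytest.approx(matrix_similarity(b, a))

    def test_matches_upper_triangle_brute_force(self, rng):
        a, b = _random_corr(rng, 6), _random_corr(rng, 6)
        assert matrix_similarity(a, b) == pytest.approx(
            brute_matrix_similarity(a.values, b.values), abs=1e-12)


class TestMantel:
    def test_identity_gives_maximal_statistic(self, rng):
        a = _random_corr(rng, 6)
        r, p = mantel_test(a, a, n_permutations=999, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_monte_carlo_approaches_exhaustive_p_for_f4(self, rng):
        a, b = _random_corr(rng, 4), _random_corr(rng, 4)
        p_exact = exhaustive_mantel_p(a.values, b.values)
        _, p_exh = mantel_test(a, b, exhaustive=True)
        assert p_exh == pytest.approx(p_exact, abs=1e-12)
        _, p_mc = mantel_test(a, b, n_permutations=40000, seed=1)
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_agrees_with_independent_library_implementation(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        a, b = _random_corr(rng, 10), _random_corr(rng, 10)
        r_ours, _ = mantel_test(a, b, n_permutations=99, seed=0)

        def as_dm(c):
            d = 1 - c.values
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            return skbio_distance.DistanceMatrix(d)

        dm_a, dm_b = as_dm(a), as_dm(b)
        r_ref, _, _ = skbio_distance.mantel(dm_a, dm_b, permutations=0)
        # corr(1-a, 1-b) == corr(a, b) on the upper triangles
        assert r_ours == pytest.approx(r_ref, abs=1e-10)

    def test_too_small_matrix_rejected(self, rng):
        a = _random_corr(rng, 2)
        with pytest.raises(ValueError, match="3"):
            mantel_test(a, a, 10, seed=0)


class TestPCoA:
    def test_perfectly_correlated_features_coincide(self):
        vals = np.array([
            [1.0, 0.999999999, 0.2],
            [0.999999999, 1.0, 0.2],
            [0.2, 0.2, 1.0],
        ])
        c = FeatureCorrelationMatrix(["a", "b", "c"], vals)
        res = pcoa(c, 2)
        np.testing.assert_allclose(res.loadings[0], res.loadings[1], atol=1e-4)

    def test_zero_correlation_simplex_eigenvalues(self):
        # d = 1 everywhere off-diagonal: regular simplex of side 1, whose
        # double-centred Gram matrix is J/2 with F-1 eigenvalues of 1/2
        f = 6
        c = FeatureCorrelationMatrix([f"f{k}" for k in range(f)], np.eye(f))
        res = pcoa(c)
        np.testing.assert_allclose(res.eigenvalues, 0.5, atol=1e-10)
        assert len(res.eigenvalues) == f - 1

    def test_euclidean_distances_reconstructed(self, rng):
        # build a correlation matrix whose 1-r distances are Euclidean by
        # checking the reconstruction on the full-rank coordinates
        a = _random_corr(rng, 5)
        res = pcoa(a)
        if res.n_negative_eigenvalues == 0:
            d = brute_pcoa_distances(res.loadings)
            np.testing.assert_allclose(d, 1 - a.values, atol=1e-8)

    def test_coordinates_centered_and_orthogonal(self, rng):
        res = pcoa(_random_corr(rng, 8), 4)
        np.testing.assert_allclose(res.loadings.mean(axis=0), 0, atol=1e-10)
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)

    def test_agrees_with_independent_library_implementation(self, rng):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        from skbio.stats.distance import DistanceMatrix

        a = _random_corr(rng, 7)
        ours = pcoa(a, 4)
        d = 1 - a.values
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ref = skbio_ordination.pcoa(DistanceMatrix(d), number_of_dimensions=4)
        np.testing.assert_allclose(ours.eigenvalues, ref.eigvals.values[:4],
                                   atol=1e-8)
        for k in range(4):
            r = brute_pearson(ours.loadings[:, k], ref.samples.values[:, k])
            assert abs(r) == pytest.approx(1.0, abs=1e-6)


class TestLoadingConcordance:
    def test_self_and_sign_flip_give_unit_diagonal(self, rng):
        res = pcoa(_random_corr(rng, 8), 4)
        import copy

        flipped = copy.deepcopy(res)
        flipped.loadings = -flipped.loadings
        for other in (res, flipped):
            conc = loading_concordance(res, other, alpha=0.001)
            np.testing.assert_allclose(np.diag(conc.abs_r), 1.0, atol=1e-10)
            assert np.diag(conc.significant).all()

    def test_invariant_to_joint_feature_permutation(self, rng):
        a, b = _random_corr(rng, 8), _random_corr(rng, 8)
        perm = rng.permutation(8)
        names = [f"f{k}" for k in range(8)]
        ap = FeatureCorrelationMatrix([names[k] for k in perm],
                                      a.values[np.ix_(perm, perm)])
        bp = FeatureCorrelationMatrix([names[k] for k in perm],
                                      b.values[np.ix_(perm, perm)])
        c1 = loading_concordance(pcoa(a, 3), pcoa(b, 3))
        c2 = loading_concordance(pcoa(ap, 3), pcoa(bp, 3))
        np.testing.assert_allclose(c1.abs_r, c2.abs_r, atol=1e-8)

    def test_mask_consistent_with_p_and_alpha(self, rng):
        conc = loading_concordance(pcoa(_random_corr(rng, 8), 3),
                                   pcoa(_random_corr(rng, 8), 3), alpha=0.05)
        np.testing.assert_array_equal(conc.significant, conc.p < 0.05)
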