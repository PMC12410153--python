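import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialconcord import (
    RatingPanel,
    compare_agreement_sets,
    exceedance_fraction,
    feature_agreement,
    fisher_z,
    group_consistency,
    intersubject_consistency,
    mean_over_raters,
    n_group_splits,
    pearson_r,
)

from oracles import (
    brute_agreement,
    brute_group_consistency,
    brute_intersubject_consistency,
    brute_pearson,
    brute_welch_t,
)


def _random_panel(rng, n_items=5, n_feat=3, n_raters=6, missing=0.1):
    cube = rng.uniform(0, 10, size=(n_items, n_feat, n_raters))
    cube[rng.random(cube.shape) < missing] = np.nan
    return RatingPanel([f"i{k}" for k in range(n_items)],
                       [f"f{k}" for k in range(n_feat)],
                       [f"r{k}" for k in range(n_raters)], cube)


class TestPearson:
    def test_self_correlation_is_one(self):
        assert pearson_r([1, 2, 5, 3], [1, 2, 5, 3]) == pytest.approx(1.0)

    def test_known_value(self):
        # hand evaluation of the product-moment formula
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_sign_reversal(self):
        x = [1.0, 4.0, 2.0, 7.0]
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_constant_input_undefined(self):
        assert np.isnan(pearson_r([1, 1, 1, 1], [1, 2, 3, 4]))

    def test_fewer_than_three_pairs_undefined(self):
        assert np.isnan(pearson_r([1, 2, np.nan, np.nan], [1, 2, 3, 4]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_with_missing(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, 8)
        y = rng.uniform(0, 10, 8)
        x[rng.random(8) < 0.2] = np.nan
        ours = pearson_r(x, y)
        theirs = brute_pearson(x, y)
        if np.isnan(theirs):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(theirs, abs=1e-12)


class TestFeatureAgreement:
    def test_identical_means_give_unit_agreement(self, tiny_panel):
        mean = mean_over_raters(tiny_panel)
        np.testing.assert_allclose(feature_agreement(mean, mean), 1.0)

    def test_constant_machine_feature_flagged(self, rng):
        panel = _random_panel(rng, missing=0)
        hm = mean_over_raters(panel)
        mm = mean_over_raters(panel)
        mm.values[:, 1] = 4.0
        out = feature_agreement(mm, hm)
        assert np.isnan(out[1]) and np.isfinite(out[0])

    def test_matches_brute_force(self, rng):
        a = mean_over_raters(_random_panel(rng))
        b = mean_over_raters(_random_panel(rng))
        np.testing.assert_allclose(
            feature_agreement(a, b), brute_agreement(a.values, b.values),
            atol=1e-10, equal_nan=True)


class TestIntersubjectConsistency:
    def test_identical_raters_give_one(self, rng):
        base = rng.uniform(0, 10, size=(6, 2))
        cube = np.repeat(base[:, :, None], 4, axis=2)
        panel = RatingPanel([f"i{k}" for k in range(6)], ["a", "b"],
                            [f"r{k}" for k in range(4)], cube)
        np.testing.assert_allclose(intersubject_consistency(panel), 1.0)

    def test_matches_leave_one_out_brute_force(self, rng):
        panel = _random_panel(rng, n_items=5, n_feat=3, n_raters=6)
        np.testing.assert_allclose(
            intersubject_consistency(panel),
            brute_intersubject_consistency(panel.ratings),
            atol=1e-10, equal_nan=True)

    def test_independent_raters_near_zero(self, rng):
        cube = rng.uniform(0, 10, size=(500, 1, 10))
        panel = RatingPanel([f"i{k}" for k in range(500)], ["f"],
                            [f"r{k}" for k in range(10)], cube)
        assert abs(intersubject_consistency(panel)[0]) < 0.05


class TestGroupConsistency:
    def test_split_count_ten_choose_five(self):
        assert n_group_splits(10, 5) == 126

    def test_split_count_general(self):
        assert n_group_splits(6, 2) == 45  # C(6,2)*C(4,2)/2

    def test_identical_raters_give_one(self, rng):
        base = rng.uniform(0, 10, size=(6, 2))
        cube = np.repeat(base[:, :, None], 4, axis=2)
        panel = RatingPanel([f"i{k}" for k in range(6)], ["a", "b"],
                            [f"r{k}" for k in range(4)], cube)
        np.testing.assert_allclose(group_consistency(panel, 2), 1.0)

    def test_two_raters_group_one_equals_pearson(self, rng):
        panel = _random_panel(rng, n_raters=2, missing=0)
        expected = [pearson_r(panel.ratings[:, j, 0], panel.ratings[:, j, 1])
                    for j in range(3)]
        np.testing.assert_allclose(group_consistency(panel, 1), expected,
                                   atol=1e-12)

    def test_matches_brute_force(self, rng):
        panel = _random_panel(rng, n_items=5, n_feat=3, n_raters=6)
        theirs, n_splits = brute_group_consistency(panel.ratings, 2)
        assert n_splits == n_group_splits(6, 2)
        np.testing.assert_allclose(group_consistency(panel, 2), theirs,
                                   atol=1e-10, equal_nan=True)

    def test_invariant_to_rater_relabeling(self, rng):
        panel = _random_panel(rng, n_raters=6, missing=0)
        perm = rng.permutation(6)
        shuffled = RatingPanel(panel.items, panel.features,
                               [panel.raters[k] for k in perm],
                               panel.ratings[:, :, perm])
        np.testing.assert_allclose(group_consistency(panel, 3),
                                   group_consistency(shuffled, 3), atol=1e-10)

    def test_too_few_raters_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            group_consistency(_random_panel(rng, n_raters=4), 5)


class TestFisherAndComparisons:
    def test_fisher_z_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
        assert fisher_z(-0.5) == pytest.approx(-fisher_z(0.5))

    def test_fisher_z_clips_unit_correlation(self):
        with pytest.warns(UserWarning, match="clipped"):
            z = fisher_z(1.0)
        assert np.isfinite(z)

    def test_identical_sets_give_t_zero_p_one(self):
        t, p, direction = compare_agreement_sets([1.0, 2, 3], [1.0, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert direction == 0

    def test_matches_hand_computed_welch(self):
        za, zb = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        t, p, direction = compare_agreement_sets(za, zb)
        t_ref, _ = brute_welch_t(za, zb)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert direction == -1

    def test_affine_rescaling_of_ratings_leaves_statistics(self, rng):
        from socialconcord import scale_ratings

        panel = _random_panel(rng, n_items=8, missing=0)
        scaled = scale_ratings(panel, (0, 100))
        np.testing.assert_allclose(intersubject_consistency(panel),
                                   intersubject_consistency(scaled), atol=1e-9)
        np.testing.assert_allclose(group_consistency(panel, 3),
                                   group_consistency(scaled, 3), atol=1e-9)


class TestExceedance:
    def test_ties_do_not_count(self):
        assert exceedance_fraction([0.5, 0.6], [0.5, 0.6]) == 0.0

    def test_uniform_exceedance(self):
        assert exceedance_fraction([0.51, 0.61], [0.5, 0.6]) == 1.0

    def test_counting_with_undefined_pairs(self):
        frac, n = exceedance_fraction([0.9, 0.8, 0.7, 0.2, np.nan],
                                      [0.5, 0.5, 0.5, 0.5, 0.5],
                                      return_n=True)
        assert n == 4
        assert frac == pytest.approx(0.75)
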