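import numpy as np
import pytest
from scipy import stats

import neurofactor as nf
from neurofactor.decoding import (
    FeaturePolicy,
    build_factor_context,
    cross_participant_cv,
    gnb_fit,
    gnb_rank,
    permutation_threshold,
    random_candidate_accuracy,
    rank_accuracy,
    select_features,
    semantic_stability_score,
    within_category_accuracy,
    within_participant_cv,
)


@pytest.fixture(scope="module")
def factor_context(default_data):
    """Context for decoding participant 0, built from participants 1-3."""
    _, dataset, _ = default_data
    return build_factor_context(dataset, [1, 2, 3])


class TestSemanticStabilityScore:
    def test_product_arithmetic(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=30)
        noise = rng.normal(size=30)
        v = 0.8 * f + noise * np.sqrt(1 - 0.64) * f.std() / noise.std()
        r = np.corrcoef(v, f)[0, 1]
        got = semantic_stability_score(v, f, 0.5)
        assert got == pytest.approx(abs(r) * 0.5, abs=1e-12)

    def test_perfect_match(self):
        f = np.arange(10.0)
        assert semantic_stability_score(f, f, 1.0) == pytest.approx(1.0)

    def test_anticorrelation_under_abs_and_signed(self):
        f = np.arange(10.0)
        assert semantic_stability_score(-f, f, 0.5) == pytest.approx(0.5)
        assert semantic_stability_score(
            -f, f, 0.5, corr_mode="signed"
        ) == pytest.approx(-0.5)

    def test_constant_profile_errors(self):
        with pytest.raises(ValueError, match="constant"):
            semantic_stability_score(np.ones(5), np.arange(5.0), 1.0)


class TestSelectFeatures:
    def test_factor_mode_yields_80_features(self, default_data, factor_context):
        _, dataset, _ = default_data
        feats = select_features(
            dataset, 0, [0, 1, 2, 3], FeaturePolicy(mode="factor"), factor_context
        )
        assert len(factor_context.volumes) == 16
        assert len(feats.voxel_ids) == 80
        assert len(np.unique(feats.provenance)) == 4

    def test_single_and_three_factor_variants(self, default_data, factor_context):
        _, dataset, _ = default_data
        ks = sorted(factor_context.factor_profiles)
        one = select_features(
            dataset, 0, None,
            FeaturePolicy(mode="factor", factors=(ks[0],)), factor_context,
        )
        assert len(one.voxel_ids) == 20  # 4 volumes x 5
        three = select_features(
            dataset, 0, None,
            FeaturePolicy(mode="factor", factors=tuple(ks[:3])), factor_context,
        )
        assert len(three.voxel_ids) == 60

    def test_stability_mode_is_pure_top_n(self, default_data):
        _, dataset, _ = default_data
        from neurofactor.preprocess import voxel_stability

        feats = select_features(dataset, 0, [0, 1], FeaturePolicy(n_features=80))
        stab = voxel_stability(dataset, 0, [0, 1], on_constant="zero")
        expected = np.argsort(-stab, kind="stable")[:80]
        np.testing.assert_array_equal(feats.voxel_ids, expected)

    def test_selection_never_touches_test_presentations(
        self, default_data, factor_context
    ):
        """Guard: overwriting held-out presentations leaves features alone."""
        _, dataset, _ = default_data
        train = [0, 1, 2, 3]
        policy = FeaturePolicy(mode="factor")
        before = select_features(dataset, 0, train, policy, factor_context)
        tampered = dataset.values.copy()
        tampered[0, 4:] = np.random.default_rng(9).normal(size=tampered[0, 4:].shape)
        ds2 = nf.ActivationDataset(
            values=tampered,
            voxel_coords=dataset.voxel_coords,
            voxel_size_mm=dataset.voxel_size_mm,
            grid_origin_mm=dataset.grid_origin_mm,
            region_labels=dataset.region_labels,
            words=dataset.words,
            grid_dims=dataset.grid_dims,
        )
        after = select_features(ds2, 0, train, policy, factor_context)
        np.testing.assert_array_equal(before.voxel_ids, after.voxel_ids)


class TestGNB:
    def test_pooled_variance_hand_case(self):
        # centred values {-1,1,-1,1}: sample variance 4/3 under n-1
        X = np.array([[-1.0], [1.0], [1.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        model = gnb_fit(X, y)
        np.testing.assert_allclose(model.means.ravel(), [0.0, 2.0])
        assert model.pooled_var[0] == pytest.approx(4 / 3)
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_zero_variance_errors_naming_feature(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        with pytest.raises(ValueError, match=r"\[0\]"):
            gnb_fit(X, np.array([0, 0, 1, 1]))

    def test_fit_invariant_to_example_order(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 3, 30)
        perm = rng.permutation(30)
        a = gnb_fit(X, y)
        b = gnb_fit(X[perm], y[perm])
        np.testing.assert_allclose(a.means, b.means, atol=1e-12)
        np.testing.assert_allclose(a.pooled_var, b.pooled_var, atol=1e-12)

    def test_rank_hand_log_likelihoods(self):
        # means 0 and 2, pooled var 1, x=0.5: log-lik -0.125 vs -1.125
        model = gnb_fit(
            np.array([[-1.0], [1.0], [1.0], [3.0]]), np.array([0, 0, 1, 1]),
            var_floor=1.0,
        )
        model.pooled_var[:] = 1.0
        ranked, log_post = gnb_rank(model, np.array([0.5]))
        assert ranked[0] == 0
        diff = log_post[0] - log_post[1]
        assert diff == pytest.approx(-0.125 - (-1.125))

    def test_equidistant_tie_broken_by_label_order(self):
        model = gnb_fit(
            np.array([[-1.0], [1.0], [1.0], [3.0]]), np.array([7, 7, 3, 3])
        )
        ranked, _ = gnb_rank(model, np.array([1.0]))  # equidistant from 0 and 2
        assert ranked.tolist() == [3, 7]  # class order = sorted labels

    def test_ranking_matches_brute_force_densities(self):
        """Oracle: direct Gaussian densities on small instances."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            n_classes = rng.integers(2, 5)
            n_feat = rng.integers(1, 4)
            X = rng.normal(size=(n_classes * 3, n_feat))
            y = np.repeat(np.arange(n_classes), 3)
            model = gnb_fit(X, y)
            x = rng.normal(size=n_feat)
            ranked, _ = gnb_rank(model, x)
            dens = np.array(
                [
                    np.prod(
                        stats.norm.pdf(
                            x, model.means[c], np.sqrt(model.pooled_var)
                        )
                    )
                    * model.priors[c]
                    for c in range(n_classes)
                ]
            )
            expected = np.lexsort((np.arange(n_classes), -dens))
            np.testing.assert_array_equal(ranked, model.classes[expected])


class TestRankAccuracy:
    @pytest.mark.parametrize("r, n, expected", [(1, 60, 1.0), (60, 60, 0.0), (2, 3, 0.5)])
    def test_values(self, r, n, expected):
        assert rank_accuracy(r, n) == expected

    def test_chance_level_is_half(self):
        # analytic: uniform rank over 1..60 has mean accuracy exactly 0.5
        accs = [rank_accuracy(r, 60) for r in range(1, 61)]
        assert np.mean(accs) == pytest.approx(0.5)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            rank_accuracy(0, 60)
        with pytest.raises(ValueError):
            rank_accuracy(61, 60)


class TestWithinParticipantCV:
    def test_fifteen_folds(self, null_data):
        _, dataset, _ = null_data
        res = within_participant_cv(dataset, 0, FeaturePolicy(n_features=40))
        assert res.fold_accuracy.shape == (15, 60)

    def test_noise_free_data_decodes_perfectly(self, noise_free_data):
        _, dataset, _ = noise_free_data
        res = within_participant_cv(dataset, 0, FeaturePolicy(n_features=80))
        assert res.mean_accuracy == 1.0

    def test_null_data_stays_at_chance(self, null_data):
        _, dataset, _ = null_data
        res = within_participant_cv(dataset, 0, FeaturePolicy(n_features=80))
        assert abs(res.mean_accuracy - 0.5) < 0.1

    def test_factor_based_decoding_with_foreign_context(
        self, default_data, factor_context
    ):
        _, dataset, _ = default_data
        res = within_participant_cv(
            dataset, 0, FeaturePolicy(mode="factor"), context=factor_context
        )
        assert res.mean_accuracy > 0.95


class TestCategoryIdentification:
    def test_top_ranked_word_scores_one(self, noise_free_data, wordset):
        _, dataset, _ = noise_free_data
        res = within_participant_cv(dataset, 0, FeaturePolicy(n_features=80))
        assert within_category_accuracy(res, wordset) == 1.0
        assert random_candidate_accuracy(res, seed=0) == 1.0

    def test_similar_candidates_are_harder(self, wordset):
        """Category-mates share semantic profiles, so identification within
        a category is harder than among random candidates."""
        cfg = nf.SyntheticConfig(
            n_participants=1, noise_sd=2.5, profile_jitter_sd=0.15, seed=31
        )
        dataset, _ = nf.generate_dataset(cfg, wordset)
        res = within_participant_cv(dataset, 0, FeaturePolicy(n_features=80))
        within = within_category_accuracy(res, wordset)
        rand5 = random_candidate_accuracy(res, seed=0)
        assert 0.5 < within < rand5


class TestCrossParticipant:
    def test_shared_code_transfers(self, default_data):
        _, dataset, _ = default_data
        results = cross_participant_cv(dataset, FeaturePolicy(n_features=80))
        for res in results.values():
            assert res.mean_accuracy > 0.95

    def test_idiosyncratic_code_collapses_to_chance(self, wordset):
        cfg = nf.SyntheticConfig(shared_code=False, seed=41)
        dataset, _ = nf.generate_dataset(cfg, wordset)
        cross = cross_participant_cv(dataset, FeaturePolicy(n_features=80))
        within = within_participant_cv(dataset, 0, FeaturePolicy(n_features=80))
        assert within.mean_accuracy > 0.9
        mean_cross = np.mean([r.mean_accuracy for r in cross.values()])
        assert abs(mean_cross - 0.5) < 0.12

    def test_own_context_is_rejected(self, default_data):
        _, dataset, _ = default_data
        ctx = build_factor_context(dataset, [0, 1])
        with pytest.raises(ValueError, match="own data"):
            cross_participant_cv(
                dataset,
                FeaturePolicy(mode="factor"),
                contexts={0: ctx, 1: ctx, 2: ctx, 3: ctx},
            )


class TestPermutationThreshold:
    def test_deterministic_and_above_half(self, null_data):
        _, dataset, _ = null_data
        fn = lambda perm: within_participant_cv(
            dataset, 0, FeaturePolicy(n_features=40), label_permutation=perm
        ).mean_accuracy
        t1 = permutation_threshold(fn, 60, 12, alpha=0.05, seed=5)
        t2 = permutation_threshold(fn, 60, 12, alpha=0.05, seed=5)
        assert t1 == t2
        assert t1 > 0.5

    def test_permuted_accuracies_centre_on_half(self, null_data):
        _, dataset, _ = null_data
        fn = lambda perm: within_participant_cv(
            dataset, 0, FeaturePolicy(n_features=40), label_permutation=perm
        ).mean_accuracy
        _, accs = permutation_threshold(
            fn, 60, 15, alpha=0.1, seed=6, return_distribution=True
        )
        assert abs(np.mean(accs) - 0.5) < 0.05
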