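import numpy as np
import pytest

import neurofactor as nf
from neurofactor.factors import (
    align_factors,
    assign_by_max_loading,
    principal_axis_factoring,
    single_level_analysis,
    solve_factor_profiles,
    varimax_criterion,
    varimax_rotate,
)


class TestPrincipalAxisFactoring:
    def test_recovers_analytic_one_factor_structure(self):
        # oracle: R built as lambda_i * lambda_j off-diagonal has exact
        # one-factor solution lambda
        lam = np.array([0.9, 0.8, 0.7])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        loadings, eigvals = principal_axis_factoring(R, 1, tol=1e-8, max_iter=5000)
        np.testing.assert_allclose(np.abs(loadings[:, 0]), lam, atol=1e-3)
        assert eigvals[0] > 1.0

    def test_identity_matrix_has_no_common_variance(self):
        loadings, _ = principal_axis_factoring(np.eye(4), 1)
        np.testing.assert_allclose(loadings, 0.0, atol=1e-6)

    def test_recovers_planted_rank_two_subspace(self):
        # two well-separated factors; oracle = eigendecomposition of the
        # noiseless reduced matrix (true communalities on the diagonal)
        L = np.array(
            [
                [0.8, 0.0], [0.8, 0.0], [0.8, 0.0],
                [0.0, 0.7], [0.0, 0.7], [0.0, 0.7],
                [0.5, 0.4], [0.4, -0.5],
            ]
        )
        R = L @ L.T
        np.fill_diagonal(R, 1.0)
        loadings, _ = principal_axis_factoring(R, 2, tol=1e-10, max_iter=10000)
        reduced = L @ L.T
        w, v = np.linalg.eigh(reduced)
        oracle = v[:, ::-1][:, :2]
        qa, _ = np.linalg.qr(loadings)
        qb, _ = np.linalg.qr(oracle)
        angles = np.linalg.svd(qa.T @ qb, compute_uv=False)
        np.testing.assert_allclose(angles, 1.0, atol=1e-4)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            principal_axis_factoring(np.array([[1.0, 0.5], [0.1, 1.0]]), 1)
        with pytest.raises(ValueError, match="diagonal"):
            principal_axis_factoring(np.array([[2.0, 0.0], [0.0, 2.0]]), 1)
        with pytest.raises(ValueError, match="k="):
            principal_axis_factoring(np.eye(3), 3)


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        L = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        rotated, _ = varimax_rotate(L)
        # unchanged up to column sign/order
        match = np.abs(rotated.T @ L)
        assert np.allclose(np.sort(match.max(axis=0)), np.sort(match.max(axis=1)))
        assert varimax_criterion(rotated) >= varimax_criterion(L) - 1e-12

    def test_rotation_matrix_orthonormal(self):
        rng = np.random.default_rng(1)
        L = rng.normal(size=(20, 4))
        rotated, R = varimax_rotate(L)
        np.testing.assert_allclose(R.T @ R, np.eye(4), atol=1e-10)
        np.testing.assert_allclose(rotated, L @ R, atol=1e-10)

    def test_communalities_preserved(self):
        rng = np.random.default_rng(2)
        L = rng.normal(size=(15, 3)) * 0.5
        rotated, _ = varimax_rotate(L)
        np.testing.assert_allclose(
            (rotated**2).sum(axis=1), (L**2).sum(axis=1), atol=1e-6
        )

    def test_demixes_45_degree_toy_against_grid_search(self):
        # oracle: exhaustive search over 2-D rotation angles
        L = np.array([[0.7, 0.7], [0.7, -0.7], [0.7, 0.7], [0.7, -0.7]])
        rotated, _ = varimax_rotate(L)
        best = -np.inf
        for theta in np.linspace(0, np.pi / 2, 20001):
            c, s = np.cos(theta), np.sin(theta)
            cand = L @ np.array([[c, -s], [s, c]])
            best = max(best, varimax_criterion(cand))
        assert varimax_criterion(rotated) >= best - 1e-6
        # near-axis loadings: each row loads on exactly one factor
        assert (np.abs(np.abs(rotated) - np.abs(rotated).max()) < 1e-6).sum() == 4


class TestSolveFactorProfiles:
    def test_identity_loadings_return_profiles(self):
        V = np.random.default_rng(3).normal(size=(3, 7))
        np.testing.assert_allclose(solve_factor_profiles(np.eye(3), V), V)

    def test_hand_least_squares(self):
        f = np.array([1.0, -2.0, 0.5])
        C = np.array([[2.0], [0.0]])
        V = np.vstack([2 * f, np.zeros(3)])
        np.testing.assert_allclose(solve_factor_profiles(C, V)[0], f, atol=1e-12)

    def test_exact_recovery_and_rank_error(self):
        rng = np.random.default_rng(4)
        C = rng.normal(size=(10, 3))
        F = rng.normal(size=(3, 6))
        np.testing.assert_allclose(solve_factor_profiles(C, C @ F), F, atol=1e-9)
        C[:, 2] = C[:, 0]
        with pytest.raises(np.linalg.LinAlgError):
            solve_factor_profiles(C, C @ F)


@pytest.mark.parametrize(
    "row, expected",
    [
        ([0.5, 0.3], 0),
        ([0.35, 0.30], None),
        ([-0.45, 0.2], 0),
        ([0.1, 0.4], 1),
    ],
)
def test_assign_by_max_loading(row, expected):
    assert assign_by_max_loading(np.array(row), threshold=0.4) == expected


class TestTwoLevelPipeline:
    def test_counts_match_configuration(self, two_level_model):
        """4 participants x 5 lobes = 20 first-level analyses of 5 factors
        each, feeding 100 profiles into the second level."""
        model = two_level_model
        assert len(model.first_level) == 20
        assert all(fm.n_factors == 5 for fm in model.first_level.values())
        assert model.second_level.loadings.shape == (100, 10)
        assert model.second_level.profiles.shape == (10, 60)

    def test_recovers_planted_profiles(self, two_level_model, default_data, common_factors):
        _, _, truth = default_data
        est = two_level_model.second_level.profiles[list(common_factors)]
        _, _, abs_r = align_factors(est, truth.factor_profiles)
        assert (abs_r >= 0.9).all()

    def test_planted_factors_reach_full_commonality(
        self, two_level_model, common_factors
    ):
        assert (two_level_model.commonality[list(common_factors)] == 4).all()

    def test_commonality_definition(self, two_level_model):
        a = two_level_model.assignments
        for k in range(two_level_model.second_level.n_factors):
            expected = a.loc[a["second_factor"] == k, "participant"].nunique()
            assert two_level_model.commonality[k] == expected

    def test_assigned_loadings_above_threshold(self, two_level_model):
        model = two_level_model
        for _, row in model.assignments.head(200).iterrows():
            fm = model.first_level[(row["participant"], row["region"])]
            i = fm.item_ids.index(row["voxel"])
            assert abs(fm.loadings[i, row["first_factor"]]) >= 0.4

    def test_first_level_eigenvalues_of_planted_factors_exceed_one(
        self, two_level_model
    ):
        for fm in two_level_model.first_level.values():
            # every lobe hosts 3-4 planted factors; at least 3 eigenvalues > 1
            assert (fm.eigenvalues > 1.0).sum() >= 3

    def test_rotation_invariance_of_fit(self, default_data):
        """||V - C F|| is identical before and after varimax rotation."""
        _, dataset, _ = default_data
        from neurofactor.factors import first_level_analysis
        from neurofactor.preprocess import (
            mean_word_profiles,
            normalize_across_words,
            VoxelProfileSet,
        )

        fm = first_level_analysis(dataset, 0, "frontal")
        prof = mean_word_profiles(dataset, 0)
        sel = VoxelProfileSet(
            profiles=prof.profiles[np.array(fm.item_ids)],
            voxel_ids=np.array(fm.item_ids),
            presentation_ids=prof.presentation_ids,
        )
        z = normalize_across_words(sel).profiles
        resid_rot = np.linalg.norm(z - fm.loadings @ fm.profiles)
        # refit with a random orthogonal rotation absorbed into F
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        L2 = fm.loadings @ Q
        F2 = solve_factor_profiles(L2, z)
        resid_q = np.linalg.norm(z - L2 @ F2)
        assert resid_rot == pytest.approx(resid_q, rel=1e-9)

    def test_duplicate_second_level_inputs_get_identical_loadings(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(12, 30))
        profiles = np.vstack([base, base[:3]])  # rows 12..14 duplicate 0..2
        model = nf.second_level_analysis(profiles, n_factors=4)
        np.testing.assert_allclose(
            model.loadings[12:15], model.loadings[:3], atol=1e-6
        )

    def test_single_level_agrees_with_two_level(
        self, default_data, two_level_model, common_factors
    ):
        _, dataset, truth = default_data
        single = single_level_analysis(
            dataset, n_voxels_per_participant=60, n_factors=6
        )
        two = two_level_model.second_level.profiles[list(common_factors)]
        _, _, abs_r = align_factors(single.profiles, two)
        assert (abs_r >= 0.85).all()
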