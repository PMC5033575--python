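import numpy as np
import pytest
from dataclasses import replace
from scipy.linalg import subspace_angles
from scipy.stats import chi2, ortho_group

import movewarp as mw
from movewarp.exceptions import DomainError, RankError, StateError


def small_dataset(seed=0, **kw):
    config = mw.FactorSimConfig(n_participants=5, n_repetitions=4, seed=seed, **kw)
    return mw.simulate_factor(config)


class TestFitFactorModel:
    def test_loglik_trace_nondecreasing(self):
        traj, _ = small_dataset(seed=1)
        model, trace = mw.fit_factor_model(traj, q=3, design="regression")
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-8 * (np.abs(trace[:-1]) + 1.0))

    def test_identification_invariants_after_fit(self):
        traj, _ = small_dataset(seed=2)
        model, _ = mw.fit_factor_model(traj, q=3, design="anova")
        q = model.q
        np.testing.assert_allclose(model.W.T @ model.W, np.eye(q), atol=1e-8)
        total = model.total_latent_cov
        np.testing.assert_allclose(total, np.diag(np.diag(total)), atol=1e-8)
        assert np.all(np.diff(np.diag(total)) <= 1e-12)  # sorted decreasing

    def test_noise_free_rank_q_data(self):
        traj, truth = small_dataset(seed=3, noise_variances=(0.0, 0.0, 0.0))
        model, _ = mw.fit_factor_model(traj, q=3, design="regression", max_iter=800)
        assert model.noise_variances.max() < 1e-6
        theta = model.theta
        P = np.eye(90) - model.W @ model.W.T
        for tr in traj:
            u = (tr.path - theta).ravel()
            assert np.abs(P @ u).max() < 1e-6

    def test_rank_error_for_excessive_q(self):
        traj, _ = small_dataset(seed=4)
        with pytest.raises(RankError):
            mw.fit_factor_model(traj, q=91, design="anova")

    def test_missing_reference_height(self):
        traj, _ = small_dataset(seed=5)
        traj = [tr for tr in traj if tr.height_level != 1]
        with pytest.raises(StateError):
            mw.fit_factor_model(traj, q=2, reference=1)

    def test_subspace_recovery(self):
        angles = []
        for seed in (1, 2, 3):
            traj, truth = mw.simulate_factor(mw.FactorSimConfig(seed=seed))
            model, _ = mw.fit_factor_model(traj, q=3, design="regression")
            angles.append(np.degrees(subspace_angles(model.W, truth["W"]).max()))
        assert np.median(angles) < 10.0


class TestIdentifyLoadings:
    def test_idempotent(self):
        traj, _ = small_dataset(seed=6)
        model, _ = mw.fit_factor_model(traj, q=3, design="regression")
        once = mw.identify_loadings(model)
        twice = mw.identify_loadings(once)
        np.testing.assert_allclose(once.W, twice.W, atol=1e-10)
        np.testing.assert_allclose(once.beta, twice.beta, atol=1e-10)
        for a, b in zip(once.level_covs, twice.level_covs):
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_random_rotation_is_undone(self):
        traj, _ = small_dataset(seed=7)
        model, _ = mw.fit_factor_model(traj, q=3, design="regression")
        Q = ortho_group.rvs(3, random_state=11)
        rotated = replace(
            model,
            W=model.W @ Q,
            beta=model.beta @ Q,
            level_covs=tuple(Q.T @ S @ Q for S in model.level_covs),
        )
        back = mw.identify_loadings(rotated)
        np.testing.assert_allclose(back.W, model.W, atol=1e-8)
        np.testing.assert_allclose(back.beta, model.beta, atol=1e-8)

    def test_loglik_unchanged_by_identification(self):
        from movewarp.factor import _Problem

        traj, _ = small_dataset(seed=13)
        model, _ = mw.fit_factor_model(traj, q=3, design="regression")
        Q = ortho_group.rvs(3, random_state=7)
        rotated = replace(
            model,
            W=model.W @ Q,
            beta=model.beta @ Q,
            level_covs=tuple(Q.T @ S @ Q for S in model.level_covs),
        )
        ident = mw.identify_loadings(rotated)
        prob = _Problem(traj, 3, "regression", 1)
        ll_rot = prob.loglik(
            rotated.W, rotated.beta.T, list(rotated.level_covs), rotated.noise_variances
        )
        ll_id = prob.loglik(
            ident.W, ident.beta.T, list(ident.level_covs), ident.noise_variances
        )
        assert ll_id == pytest.approx(ll_rot, abs=1e-8)

    def test_total_curve_covariance_conserved(self):
        # the fitted marginal covariance of one curve is invariant under the
        # identification rotation
        traj, _ = small_dataset(seed=8)
        model, _ = mw.fit_factor_model(traj, q=3, design="regression")
        Q = ortho_group.rvs(3, random_state=4)
        rotated = replace(
            model,
            W=model.W @ Q,
            beta=model.beta @ Q,
            level_covs=tuple(Q.T @ S @ Q for S in model.level_covs),
        )
        ident = mw.identify_loadings(rotated)
        cov_a = model.W @ model.total_latent_cov @ model.W.T
        cov_b = ident.W @ ident.total_latent_cov @ ident.W.T
        np.testing.assert_allclose(cov_a, cov_b, atol=1e-8)

    def test_reduces_to_probabilistic_pca_on_condition_means(self):
        # with the latent levels silenced and beta free, the fitted loadings
        # span the principal subspace of the mean-corrected data
        zero = (1e-6, 1e-6, 1e-6)
        beta = np.array([[3.0, 0.5, 0.0], [0.5, -2.0, 0.0]])  # rank-2 height effect
        config = mw.FactorSimConfig(
            n_participants=4, n_repetitions=3, seed=9, design="anova", beta=beta,
            participant_sd=zero, reaction_sd=zero, repetition_sd=zero,
            noise_variances=(1e-10, 1e-10, 1e-10),
        )
        traj, truth = mw.simulate_factor(config)
        model, _ = mw.fit_factor_model(traj, q=2, design="anova", max_iter=800)
        U = np.stack([(tr.path - model.theta).ravel() for tr in traj])
        _, _, Vt = np.linalg.svd(U - U.mean(axis=0), full_matrices=False)
        angle = subspace_angles(model.W, Vt[:2].T).max()
        assert angle < 1e-3


class TestVarianceExplained:
    def test_shares_sum_to_hundred_without_noise(self):
        traj, _ = small_dataset(seed=10, noise_variances=(0.0, 0.0, 0.0))
        model, _ = mw.fit_factor_model(traj, q=3, design="regression", max_iter=800)
        shares = mw.variance_explained(model, traj)
        assert shares.sum() == pytest.approx(100.0, abs=0.1)

    def test_matches_generating_composition(self):
        # compare fitted shares against the share decomposition of the
        # realized latent draws (the population shares carry Monte-Carlo
        # noise of several points at 10 participants, which would test the
        # luck of the draw rather than the estimator)
        diffs = []
        for seed in range(1, 7):
            config = mw.FactorSimConfig(seed=seed)
            traj, truth = mw.simulate_factor(config)
            model, _ = mw.fit_factor_model(traj, q=3, design="regression")
            shares = np.sort(mw.variance_explained(model, traj))[::-1]
            scores = []
            for tr in traj:
                x = mw.height_design_row(tr.height_level, "regression")
                scores.append(
                    x @ truth["beta"]
                    + truth["z_participant"][tr.participant_id]
                    + truth["z_reaction"][(tr.participant_id, tr.height_level)]
                    + truth["z_repetition"][
                        (tr.participant_id, tr.repetition_id, tr.height_level)
                    ]
                )
            v = np.var(np.stack(scores), axis=0, ddof=0)
            realized = np.sort(100 * v / (v.sum() + 30 * truth["noise_variances"].sum()))[::-1]
            diffs.append(np.abs(shares - realized).max())
        assert np.median(diffs) < 2.0


class TestLRT:
    def test_null_statistic_is_small_and_valid(self):
        traj, _ = mw.simulate_factor(
            mw.FactorSimConfig(n_participants=8, n_repetitions=3, seed=21, design="regression")
        )
        stat, p = mw.lrt_height_design(traj, q=3)
        assert stat >= 0.0
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(float(chi2.sf(stat, 3)))

    def test_power_against_nonlinear_height_effect(self):
        beta = np.array([[4.0, 1.0, 0.0], [-3.0, -1.0, 0.0]])  # far from linear
        for seed in (1, 2, 3):
            traj, _ = mw.simulate_factor(
                mw.FactorSimConfig(
                    n_participants=6, n_repetitions=4, seed=seed, design="anova", beta=beta
                )
            )
            stat, p = mw.lrt_height_design(traj, q=3)
            assert p < 0.001


class TestLevelEllipsoids:
    def _model(self):
        traj, _ = small_dataset(seed=12)
        model, _ = mw.fit_factor_model(traj, q=3, design="regression")
        return model

    def test_zero_covariance_degenerates_to_point(self):
        model = self._model()
        degenerate = replace(
            model, level_covs=(np.zeros((3, 3)), model.level_covs[1], model.level_covs[2])
        )
        ell = mw.level_ellipsoids(degenerate, "participant", time_index=10)
        np.testing.assert_allclose(ell.radii, 0.0, atol=1e-12)

    def test_isotropic_radii_match_chi2_quantile(self):
        # craft loadings whose three rows at one time point are the identity
        W = np.zeros((90, 3))
        W[27:30, :] = np.eye(3)  # time point 10, coordinate-fastest layout
        model = mw.FactorModel(
            theta=np.zeros((30, 3)),
            W=W,
            beta=np.zeros((1, 3)),
            design="regression",
            level_covs=(np.eye(3), np.zeros((3, 3)), np.zeros((3, 3))),
            noise_variances=np.full(3, 0.1),
        )
        ell = mw.level_ellipsoids(model, "participant", time_index=10, coverage=0.95)
        np.testing.assert_allclose(ell.cov, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(ell.radii, np.sqrt(chi2.ppf(0.95, 3)), atol=1e-12)
        assert ell.radii[0] == pytest.approx(np.sqrt(7.814727903), abs=1e-6)

    def test_volume_equivariant_under_spatial_rotation(self):
        model = self._model()
        ell = mw.level_ellipsoids(model, "repetition", time_index=15)
        R = ortho_group.rvs(3, random_state=3)
        W_rot = np.einsum("ab,tbq->taq", R, model.W.reshape(30, 3, 3)).reshape(90, 3)
        rotated = replace(model, W=W_rot)
        ell_rot = mw.level_ellipsoids(rotated, "repetition", time_index=15)
        assert np.prod(ell_rot.radii) == pytest.approx(np.prod(ell.radii), rel=1e-8)

    def test_domain_errors(self):
        model = self._model()
        with pytest.raises(DomainError):
            mw.level_ellipsoids(model, "participant", 10, coverage=1.5)
        with pytest.raises(DomainError):
            mw.level_ellipsoids(model, "nonsense", 10)
        with pytest.raises(DomainError):
            mw.level_ellipsoids(model, "participant", 31)
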