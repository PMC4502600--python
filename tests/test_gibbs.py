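"""Gibbs sampler unit and property tests: truncated-normal latent draws,
conjugate coefficient updates, parameter-expanded correlation draws, and the
full fit against independent oracles (GLS, probit MLE, closed forms)."""

import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import invwishart, ks_2samp

import jointprobit as jp
from jointprobit.datatypes import (
    DataValidationError,
    McmcSettings,
    ModelSpec,
    OccurrenceMatrix,
    QuasiSeparationWarning,
    nearest_correlation,
)
from jointprobit.gibbs import _sample_inverse_wishart, sample_correlation

from conftest import make_design, quick_settings


class TestSampleLatent:
    def test_all_absent_gives_nonpositive_latents(self, rng):
        n, J = 50, 3
        Y = np.zeros((n, J))
        X = np.ones((n, 1))
        B = np.zeros((1, J))
        z = jp.sample_latent(Y, X, B, np.eye(J), rng)
        assert np.all(z <= 0)

    def test_half_normal_mean_under_identity(self, rng):
        # y=1, mean 0, R=I: latents are standard half-normals
        n = 100_000
        z = jp.sample_latent(np.ones((n, 1)), np.ones((n, 1)), np.zeros((1, 1)), np.eye(1), rng)
        expect = np.sqrt(2 / np.pi)
        mc_se = np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        assert abs(z.mean() - expect) < 3 * mc_se

    def test_identity_correlation_means_ignore_other_taxa(self, rng):
        # under R=I the conditional mean is x.beta_j whatever the other columns hold
        n = 2000
        X = np.column_stack([np.ones(n), np.linspace(-2, 2, n)])
        B = np.array([[0.3, -0.2], [0.5, 0.7]])
        Y = np.ones((n, 2))
        draws = np.stack([
            jp.sample_latent(Y, X, B, np.eye(2), np.random.default_rng(s)) for s in range(200)
        ])
        mu = X @ B
        # E[z | z>0] = mu + phi(mu)/Phi(mu); check empirically per column
        from scipy.stats import norm
        expect = mu + norm.pdf(mu) / norm.cdf(mu)
        diff = np.abs(draws.mean(axis=0) - expect)
        assert diff.mean() < 0.05  # per-cell MC noise ~0.04 sd at 200 sweeps
        assert np.quantile(diff, 0.99) < 0.2

    def test_sign_constraint_respected_under_correlation(self, rng):
        n, J = 300, 4
        Y = (rng.random((n, J)) < 0.4).astype(float)
        R = nearest_correlation(np.eye(J) + 0.4 - 0.4 * np.eye(J), eig_floor=0.05)
        z = jp.sample_latent(Y, np.ones((n, 1)), np.zeros((1, J)), R, rng)
        assert np.all((z > 0) == (Y > 0))

    def test_rejects_non_positive_definite_correlation(self, rng):
        R = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(DataValidationError):
            jp.sample_latent(np.ones((5, 2)), np.ones((5, 1)), np.zeros((1, 2)), R, rng)


class TestSampleCoefficients:
    def test_flat_prior_identity_R_matches_least_squares(self, rng):
        n = 500
        X = make_design(n, 2, seed=5)
        Z = rng.standard_normal((n, 2)) + X.values @ np.array([[0.1, 0.4], [1.0, -1.0], [0.2, 0.0]])
        draws = np.stack([
            jp.sample_coefficients(Z, X, np.eye(2), 0.0, np.random.default_rng(s))
            for s in range(400)
        ])
        ols = np.linalg.lstsq(X.values, Z, rcond=None)[0]
        assert np.allclose(draws.mean(axis=0), ols, atol=0.02)

    def test_point_mass_prior_returns_zeros(self, rng):
        Z = rng.standard_normal((50, 2))
        X = make_design(50, 1, seed=2)
        B = jp.sample_coefficients(Z, X, np.eye(2), np.inf, rng)
        assert np.all(B == 0)

    def test_structural_zeros_follow_model_spec(self, rng):
        X = make_design(100, 2, seed=9)
        spec = ModelSpec(
            model_type="full",
            per_taxon_covariates={"a": ["x1"], "b": ["x2"]},
            forced_terms=[],
        )
        Z = rng.standard_normal((100, 2))
        B = jp.sample_coefficients(Z, X, np.eye(2), 0.01, rng, spec=spec, taxon_names=["a", "b"])
        # taxon a excludes x2 (row 2), taxon b excludes x1 (row 1)
        assert B[2, 0] == 0 and B[1, 1] == 0
        assert B[1, 0] != 0 and B[2, 1] != 0


class TestSampleCorrelation:
    def test_single_taxon_is_trivially_one(self, rng):
        R, d = sample_correlation(np.ones((10, 1)), rng)
        assert R.shape == (1, 1) and R[0, 0] == 1.0

    def test_recovers_known_residual_correlation(self, rng):
        Rstar = np.array([[1.0, 0.6], [0.6, 1.0]])
        E = rng.standard_normal((2000, 2)) @ np.linalg.cholesky(Rstar).T
        draws = np.array([sample_correlation(E, rng)[0][0, 1] for _ in range(300)])
        assert abs(draws.mean() - 0.6) < 0.05

    def test_draws_are_valid_correlation_matrices(self, rng):
        E = rng.standard_normal((60, 5))
        for _ in range(25):
            R, _ = sample_correlation(E, rng)
            assert np.allclose(R, R.T)
            assert np.allclose(np.diag(R), 1.0)
            assert np.linalg.eigvalsh(R)[0] > 0

    def test_bartlett_inverse_wishart_matches_scipy_mean(self, rng):
        df, S = 12, np.array([[2.0, 0.4], [0.4, 1.5]])
        draws = np.stack([_sample_inverse_wishart(df, S, rng)[0] for _ in range(6000)])
        assert np.allclose(draws.mean(axis=0), invwishart(df, S).mean(), atol=0.03)

    def test_inverse_pair_is_consistent(self, rng):
        S, S_inv = _sample_inverse_wishart(9, np.eye(3), rng)
        assert np.allclose(S @ S_inv, np.eye(3), atol=1e-10)


class TestFit:
    def test_reproducible_bit_identical(self, small_joint_data):
        Y, X, _, _, spec = small_joint_data
        s1 = jp.fit(Y, X, spec, quick_settings(11, iters=800, burn=200), check_convergence=False)
        s2 = jp.fit(Y, X, spec, quick_settings(11, iters=800, burn=200), check_convergence=False)
        assert np.array_equal(s1.coefficients, s2.coefficients)
        assert np.array_equal(s1.correlations, s2.correlations)

    def test_null_intercept_matches_probit_of_prevalence(self):
        # single-round single-area null model: intercept posterior ~ Phi^-1(prevalence)
        r = np.random.default_rng(0)
        n = 1500
        Y = OccurrenceMatrix(
            (r.random((n, 2)) < [0.3, 0.6]).astype(float),
            [f"s{i}" for i in range(n)], ["a", "b"],
        )
        X = make_design(n, 0, seed=1)
        spec = ModelSpec(model_type="null")
        s = jp.fit(Y, X, spec, quick_settings(5, iters=1500, burn=500), check_convergence=False)
        post_mean = s.mean_coefficients()[0]
        expect = ndtri(Y.prevalence())
        assert np.allclose(post_mean, expect, atol=0.12)

    def test_environment_only_posterior_matches_probit_mle(self):
        # independent-probit data: posterior mean within 3 posterior sd of the MLE
        r = np.random.default_rng(8)
        n = 1000
        X = make_design(n, 2, seed=8)
        B_true = np.array([[0.2, -0.4], [0.8, 0.5], [-0.5, 1.0]])
        Y = jp.simulate_community(X, B_true, np.eye(2), seed=21)
        spec = ModelSpec(
            model_type="environment_only",
            per_taxon_covariates={t: ["x1", "x2"] for t in Y.taxon_names},
            forced_terms=[],
        )
        s = jp.fit(Y, X, spec, quick_settings(9, iters=3000, burn=1000), check_convergence=False)
        pooled = s.pooled_coefficients()
        for j in range(2):
            mle, _ = jp.probit_mle(Y.values[:, j], X)
            post_mean = pooled[:, :, j].mean(axis=0)
            post_sd = pooled[:, :, j].std(axis=0)
            assert np.all(np.abs(post_mean - mle) < 3 * post_sd)

    def test_identity_constrained_fit_equals_single_taxon_fit(self):
        # marginal coefficient posterior of a taxon in a 2-taxon identity-R fit
        # is the same distribution as fitting that taxon alone (KS at alpha=0.01)
        r = np.random.default_rng(3)
        n = 300
        X = make_design(n, 1, seed=14)
        B_true = np.array([[0.1, -0.2], [0.7, 0.4]])
        Y = jp.simulate_community(X, B_true, np.eye(2), seed=15)
        spec2 = ModelSpec(
            model_type="environment_only",
            per_taxon_covariates={t: ["x1"] for t in Y.taxon_names},
            forced_terms=[],
        )
        # thin enough that pooled draws are near-independent, as KS assumes
        st = McmcSettings(seed=100, n_iterations=5500, n_burnin=500, thin=5, n_chains=2)
        joint = jp.fit(Y, X, spec2, st, check_convergence=False)
        Y1 = OccurrenceMatrix(Y.values[:, :1], Y.site_ids, Y.taxon_names[:1])
        spec1 = ModelSpec(
            model_type="environment_only",
            per_taxon_covariates={Y.taxon_names[0]: ["x1"]},
            forced_terms=[],
        )
        st2 = McmcSettings(seed=200, n_iterations=5500, n_burnin=500, thin=5, n_chains=2)
        alone = jp.fit(Y1, X, spec1, st2, check_convergence=False)
        a = joint.pooled_coefficients()[:, 1, 0]
        b = alone.pooled_coefficients()[:, 1, 0]
        assert a.size == 2000 and b.size == 2000
        assert ks_2samp(a, b).pvalue > 0.01

    def test_correlation_draw_invariants_hold_for_every_kept_draw(self, small_joint_data):
        Y, X, _, _, spec = small_joint_data
        s = jp.fit(Y, X, spec, quick_settings(17, iters=600, burn=100, thin=2), check_convergence=False)
        Rs = s.pooled_correlations()
        assert np.allclose(Rs, np.swapaxes(Rs, 1, 2))
        assert np.allclose(Rs[:, 0, 0], 1.0) and np.allclose(Rs[:, 1, 1], 1.0)
        assert all(np.linalg.eigvalsh(R)[0] > 0 for R in Rs)
        assert np.all(np.abs(Rs[:, 0, 1]) < 1)

    def test_recovers_planted_correlation(self, small_joint_data):
        Y, X, B_true, R_true, spec = small_joint_data
        s = jp.fit(Y, X, spec, quick_settings(23, iters=3000, burn=1000), check_convergence=False)
        r_draws = s.pooled_correlations()[:, 0, 1]
        lo, hi = np.quantile(r_draws, [0.025, 0.975])
        assert lo < 0.5 < hi
        assert abs(r_draws.mean() - 0.5) < 0.15

    def test_recovery_across_datasets_small_scale(self):
        """Posterior-mean correlations track the truth across replicate
        datasets (few-replicate sanity bound; the full-scale recovery
        experiment runs in the acceptance suite)."""
        from jointprobit.simulate import make_recovery_dataset

        maes = []
        for seed in range(4):
            Y, X, spec, truth = make_recovery_dataset(seed, n_sites=500, n_taxa=4)
            s = jp.fit(Y, X, spec, quick_settings(seed, iters=2500, burn=500, thin=5),
                       check_convergence=False)
            Rm = s.pooled_correlations().mean(axis=0)
            iu = np.triu_indices(4, 1)
            maes.append(np.abs(Rm[iu] - truth.R_true[iu]).mean())
        # information-limited accuracy at this size is ~0.08-0.12 per dataset
        assert np.mean(maes) < 0.13

    def test_degenerate_taxon_warns_of_quasi_separation(self):
        n = 60
        X = make_design(n, 0, seed=4)
        Y = OccurrenceMatrix(
            np.column_stack([np.zeros(n), (np.random.default_rng(2).random(n) < 0.5).astype(float)]),
            [f"s{i}" for i in range(n)], ["never", "common"],
        )
        with pytest.warns(QuasiSeparationWarning):
            jp.fit(Y, X, ModelSpec(model_type="null"),
                   quick_settings(3, iters=200, burn=50, thin=1, chains=1),
                   check_convergence=False)

    def test_invalid_settings_rejected(self):
        with pytest.raises(DataValidationError):
            McmcSettings(seed=1, n_iterations=100, n_burnin=100)
        with pytest.raises(DataValidationError):
            McmcSettings(seed=1, n_iterations=100, n_burnin=10, thin=0)
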