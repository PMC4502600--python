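"""Likelihood/deviance/DIC tests against closed forms and independent-probit
oracles."""

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import multivariate_normal

import jointprobit as jp
from jointprobit.comparison import GhkSettings, orthant_probabilities
from jointprobit.datatypes import (
    DataValidationError,
    McmcSettings,
    ModelSpec,
    OccurrenceMatrix,
    PosteriorSamples,
    nearest_correlation,
)

from conftest import make_design

MC = GhkSettings(n_draws=10_000, seed=7)


class TestOrthantProbability:
    def test_independent_centred_bivariate_is_quarter(self):
        assert np.isclose(jp.orthant_probability([0, 0], np.eye(2), [1, 1], MC), 0.25)

    @pytest.mark.parametrize("rho, expect", [(0.5, 1 / 3), (0.7, 0.25 + np.arcsin(0.7) / (2 * np.pi))])
    def test_correlated_bivariate_closed_form(self, rho, expect):
        R = np.array([[1.0, rho], [rho, 1.0]])
        assert abs(jp.orthant_probability([0, 0], R, [1, 1], MC) - expect) < 1e-3

    def test_univariate_is_phi(self):
        assert np.isclose(jp.orthant_probability([1.6449], np.eye(1), [1], MC), 0.95, atol=1e-4)

    def test_matches_scipy_mvn_cdf_oracle(self):
        # independent route: scipy's MVN CDF on the negative-orthant pattern
        R = nearest_correlation(np.array([[1, 0.4, -0.2], [0.4, 1, 0.3], [-0.2, 0.3, 1.0]]))
        mu = np.array([0.3, -0.5, 0.2])
        y = np.array([0, 1, 0])
        # flip signs so the event becomes an all-below-zero MVN CDF
        s = np.where(y > 0, -1.0, 1.0)
        Rf = R * np.outer(s, s)
        expect = multivariate_normal(mean=np.zeros(3), cov=Rf).cdf(-s * mu)
        got = jp.orthant_probability(mu, R, y, MC)
        assert abs(got - expect) < 2e-3

    def test_sign_patterns_sum_to_one(self):
        R = nearest_correlation(np.array([
            [1.0, 0.4, 0.2, -0.3],
            [0.4, 1.0, 0.3, 0.1],
            [0.2, 0.3, 1.0, 0.25],
            [-0.3, 0.1, 0.25, 1.0],
        ]))
        mu = np.array([0.2, -0.1, 0.4, 0.0])
        total = 0.0
        for bits in range(16):
            y = np.array([(bits >> k) & 1 for k in range(4)], float)
            total += jp.orthant_probability(mu, R, y, MC)
        assert abs(total - 1.0) < 1e-3

    def test_fixed_seed_deterministic_and_stable_in_m(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        a = jp.orthant_probability([0, 0], R, [1, 1], GhkSettings(10_000, seed=3))
        b = jp.orthant_probability([0, 0], R, [1, 1], GhkSettings(10_000, seed=3))
        c = jp.orthant_probability([0, 0], R, [1, 1], GhkSettings(20_000, seed=3))
        assert a == b
        assert abs(a - c) < 1e-3

    def test_non_positive_definite_rejected(self):
        with pytest.raises(DataValidationError):
            jp.orthant_probability([0, 0], np.array([[1.0, 1.1], [1.1, 1.0]]), [1, 1], MC)


def _toy_Y_X(n=10, J=1, prevalence=0.5, seed=0):
    vals = np.zeros((n, J))
    vals[: int(n * prevalence)] = 1.0
    Y = OccurrenceMatrix(vals, [f"s{i}" for i in range(n)], [f"t{j}" for j in range(J)])
    X = make_design(n, 0, seed=seed)
    return Y, X


class TestDeviance:
    def test_null_even_prevalence_closed_form(self):
        Y, X = _toy_Y_X(n=10, prevalence=0.5)
        d = jp.deviance(Y, X, np.zeros((1, 1)), np.eye(1), MC)
        assert np.isclose(d, -2 * 10 * np.log(0.5))

    def test_perfect_prediction_limit_is_zero(self):
        # huge correctly-signed linear predictor drives the deviance to 0
        from jointprobit.datatypes import DesignMatrix

        Y, _ = _toy_Y_X(n=20, prevalence=0.5)
        X = DesignMatrix(
            np.column_stack([np.ones(20), Y.values[:, 0]]),
            ["intercept", "ind"], ["intercept", "binary"],
        )
        B = np.array([[-20.0], [40.0]])
        assert jp.deviance(Y, X, B, np.eye(1), MC) < 1e-6

    def test_identity_matches_independent_probit_oracle(self):
        rng = np.random.default_rng(4)
        n = 300
        X = make_design(n, 2, seed=4)
        B = np.array([[0.2, -0.1], [0.6, 0.3], [-0.4, 0.8]])
        Y = jp.simulate_community(X, B, np.eye(2), seed=12)
        joint = jp.deviance(Y, X, B, np.eye(2), MC)
        per_taxon = 0.0
        for j in range(2):
            p = ndtr(X.values @ B[:, j])
            yj = Y.values[:, j]
            per_taxon += -2 * np.sum(yj * np.log(p) + (1 - yj) * np.log(1 - p))
        assert np.isclose(joint, per_taxon, rtol=1e-12)

    def test_per_taxon_conditional_reduces_deviance_with_strong_correlation(self):
        rng = np.random.default_rng(6)
        n = 800
        X = make_design(n, 0, seed=6)
        R = np.array([[1.0, 0.9], [0.9, 1.0]])
        B = np.zeros((1, 2))
        Y = jp.simulate_community(X, B, R, seed=13)
        mc = GhkSettings(4000, seed=5)
        cond = jp.per_taxon_deviance(Y, X, B, R, mc)
        marg = jp.per_taxon_deviance(Y, X, B, np.eye(2), mc)
        assert cond[0] < marg[0]
        # and under identity, conditional deviances sum to the joint
        d_ident = jp.deviance(Y, X, B, np.eye(2), mc)
        assert np.isclose(jp.per_taxon_deviance(Y, X, B, np.eye(2), mc).sum(), d_ident)


def _samples_from_draws(B_draws, Y, X, model_type="null"):
    """Wrap explicit coefficient draws as PosteriorSamples (identity R)."""
    B_draws = np.asarray(B_draws, float)
    n_draws = B_draws.shape[0]
    settings = McmcSettings(seed=0, n_iterations=n_draws, n_burnin=0, thin=1, n_chains=1)
    return PosteriorSamples(
        coefficients=B_draws[None],
        correlations=None,
        model_spec=ModelSpec(model_type=model_type),
        settings=settings,
        covariate_names=X.covariate_names,
        taxon_names=Y.taxon_names,
    )


class TestDic:
    def test_degenerate_posterior_gives_zero_pd(self):
        Y, X = _toy_Y_X(n=8, prevalence=0.5)
        draws = np.zeros((5, 1, 1))
        s = _samples_from_draws(draws, Y, X)
        res = jp.dic(s, Y, X, MC)
        assert np.isclose(res.effective_parameters, 0.0, atol=1e-10)
        assert np.isclose(res.dic, res.deviance_at_mean)

    def test_matches_hand_computation_on_two_fixed_draws(self):
        # 1 taxon, 2 sites (one presence, one absence), two explicit draws
        Y = OccurrenceMatrix(np.array([[1.0], [0.0]]), ["s1", "s2"], ["t"])
        from jointprobit.datatypes import DesignMatrix
        X = DesignMatrix(np.ones((2, 1)), ["intercept"], ["intercept"])
        b1, b2 = 0.3, -0.2
        s = _samples_from_draws(np.array([[[b1]], [[b2]]]), Y, X)
        res = jp.dic(s, Y, X, MC)

        def dev(b):
            return -2 * (np.log(ndtr(b)) + np.log(1 - ndtr(b)))

        dbar = 0.5 * (dev(b1) + dev(b2))
        dhat = dev(0.5 * (b1 + b2))
        assert np.isclose(res.mean_deviance, dbar)
        assert np.isclose(res.dic, 2 * dbar - dhat)

    def test_needs_at_least_two_draws(self):
        Y, X = _toy_Y_X()
        s = _samples_from_draws(np.zeros((1, 1, 1)), Y, X)
        with pytest.raises(DataValidationError):
            jp.dic(s, Y, X, MC)


class TestProportionExplained:
    def test_null_against_itself_explains_nothing(self):
        Y, X = _toy_Y_X(n=40, prevalence=0.4)
        b0 = float(np.mean([0.0]))
        draws = np.full((6, 1, 1), -0.25)
        s = _samples_from_draws(draws, Y, X)
        summary = jp.proportion_explained(s, s, Y, X, MC)
        assert np.allclose(summary.per_taxon_proportion_explained, 0.0, atol=1e-12)
        assert np.isclose(summary.community_proportion_explained, 0.0, atol=1e-12)

    def test_strong_environment_signal_explains_most_deviance(self):
        rng = np.random.default_rng(10)
        n = 400
        X = make_design(n, 1, seed=10)
        B_true = np.array([[0.0], [2.5]])
        Y = jp.simulate_community(X, B_true, np.eye(1), seed=30)
        null_s = _samples_from_draws(np.array([[[-0.05], [0.0]], [[0.05], [0.0]]]), Y, X)
        env_s = _samples_from_draws(np.array([[[0.0], [2.4]], [[0.0], [2.6]]]), Y, X,
                                    model_type="environment_only")
        env_s.model_spec.per_taxon_covariates = {Y.taxon_names[0]: ["x1"]}
        summary = jp.proportion_explained(env_s, null_s, Y, X, MC)
        assert summary.per_taxon_proportion_explained[0] > 0.5
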