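"""Model comparison: multivariate probit likelihood, deviance and DIC.

The likelihood of one site's occurrence pattern y_i is the orthant
probability P(sign pattern of MVN(x_i B, R) = y_i).  With R = I it is the
exact product of univariate probit terms; otherwise it is estimated with the
GHK sequential importance sampler (seeded, antithetic uniforms, shared across
sites so repeated evaluations are comparable).

Deviance is -2 sum_i log p(y_i); per-taxon deviance under a correlated model
is defined conditionally, -2 sum_i log p(y_ij | y_i,-j), which lets the
correlation matrix inform per-taxon predictions and reduces to the marginal
probit deviance when R = I.  DIC uses the integrated (GHK) likelihood:
DIC = 2 Dbar - D(theta_bar), with theta_bar the element-wise posterior mean
of B and the posterior mean of R projected to the nearest correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .datatypes import (
    DataValidationError,
    DesignMatrix,
    OccurrenceMatrix,
    PosteriorSamples,
    nearest_correlation,
)

__all__ = [
    "GhkSettings",
    "DicResult",
    "DevianceSummary",
    "orthant_probability",
    "orthant_probabilities",
    "deviance",
    "per_taxon_deviance",
    "proportion_explained",
    "dic",
]

#: probabilities are floored here before taking logs
PROB_FLOOR = 1e-300

_TINY = 1e-15


@dataclass(frozen=True)
class GhkSettings:
    """Monte-Carlo settings for the GHK orthant-probability simulator."""

    n_draws: int = 5000
    seed: int = 0
    antithetic: bool = True

    def uniforms(self, n_taxa: int) -> np.ndarray:
        """(n_taxa, M) uniforms, antithetic pairs interleaved if requested."""
        rng = np.random.default_rng(self.seed)
        if self.antithetic:
            half = max(1, self.n_draws // 2)
            u = rng.random((n_taxa, half))
            return np.concatenate([u, 1.0 - u], axis=1)
        return rng.random((n_taxa, self.n_draws))


@dataclass
class DicResult:
    mean_deviance: float
    deviance_at_mean: float

    @property
    def effective_parameters(self) -> float:
        return self.mean_deviance - self.deviance_at_mean

    @property
    def dic(self) -> float:
        return 2.0 * self.mean_deviance - self.deviance_at_mean


@dataclass
class DevianceSummary:
    taxon_names: list[str]
    per_taxon_null_deviance: np.ndarray
    per_taxon_residual_deviance: np.ndarray

    @property
    def per_taxon_proportion_explained(self) -> np.ndarray:
        return 1.0 - self.per_taxon_residual_deviance / self.per_taxon_null_deviance

    @property
    def community_proportion_explained(self) -> float:
        # ratio of summed deviances: weights taxa by information content
        return 1.0 - self.per_taxon_residual_deviance.sum() / self.per_taxon_null_deviance.sum()


def _is_identity(R: np.ndarray) -> bool:
    return np.allclose(R, np.eye(R.shape[0]), atol=1e-12)


def _check_pd(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, float)
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise DataValidationError("correlation matrix is not positive definite")
    return R


def orthant_probabilities(
    Mu: np.ndarray, R: np.ndarray, Y: np.ndarray, mc: GhkSettings
) -> np.ndarray:
    """Orthant probabilities for many sites at once.

    Mu and Y are (n, J); returns P(sign pattern of MVN(mu_i, R) = y_i) per
    site.  Exact Phi-product when R = I, GHK otherwise (uniform draws shared
    across sites).
    """
    Mu = np.atleast_2d(np.asarray(Mu, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if Mu.shape != Y.shape or Mu.shape[1] != R.shape[0]:
        raise DataValidationError("dimension mismatch in orthant probability")
    R = _check_pd(R)
    pos = Y > 0
    if _is_identity(R):
        p_one = ndtr(Mu)
        return np.prod(np.where(pos, p_one, 1.0 - p_one), axis=1)
    n, J = Mu.shape
    L = np.linalg.cholesky(R)
    U = mc.uniforms(J)
    M = U.shape[1]
    # chunk over sites so the (chunk, M, J) workspace stays modest
    chunk = max(1, int(2e7 // (M * J)))
    out = np.empty(n)
    for s in range(0, n, chunk):
        e = slice(s, min(s + chunk, n))
        out[e] = _ghk_chunk(Mu[e], pos[e], L, U)
    return out


def _ghk_chunk(Mu, pos, L, U):
    n, J = Mu.shape
    M = U.shape[1]
    prob = np.ones((n, M))
    E = np.empty((n, M, J))
    for j in range(J):
        partial = np.zeros((n, M)) if j == 0 else E[:, :, :j] @ L[j, :j]
        t = (-Mu[:, j, None] - partial) / L[j, j]
        q = ndtr(t)
        pj = np.where(pos[:, j, None], 1.0 - q, q)
        start = np.where(pos[:, j, None], q, 0.0)
        draw = np.clip(start + U[j][None, :] * pj, _TINY, 1.0 - _TINY)
        E[:, :, j] = ndtri(draw)
        prob *= pj
    return prob.mean(axis=1)


def orthant_probability(mu, R, y, mc: GhkSettings = GhkSettings()) -> float:
    """Probability that the sign pattern of MVN(mu, R) matches y."""
    mu = np.atleast_1d(np.asarray(mu, float))
    y = np.atleast_1d(np.asarray(y, float))
    return float(orthant_probabilities(mu[None, :], R, y[None, :], mc)[0])


def _site_log_probs(Y, X, B, R, mc) -> np.ndarray:
    Mu = X.values @ B
    p = orthant_probabilities(Mu, R, Y.values, mc)
    if np.any(p < PROB_FLOOR):
        warnings.warn("site probabilities floored at 1e-300 before log")
        p = np.maximum(p, PROB_FLOOR)
    return np.log(p)


def deviance(
    Y: OccurrenceMatrix, X: DesignMatrix, B: np.ndarray, R: np.ndarray,
    mc: GhkSettings = GhkSettings(),
) -> float:
    """Joint residual deviance, -2 sum_i log p(y_i | B, R)."""
    return float(-2.0 * _site_log_probs(Y, X, B, R, mc).sum())


def per_taxon_deviance(
    Y: OccurrenceMatrix, X: DesignMatrix, B: np.ndarray, R: np.ndarray,
    mc: GhkSettings = GhkSettings(),
) -> np.ndarray:
    """Conditional per-taxon deviance, -2 sum_i log p(y_ij | y_i,-j).

    Computed as the joint orthant probability divided by the orthant
    probability of the pattern with taxon j marginalised out; equal to the
    marginal probit deviance when R = I.
    """
    R = np.asarray(R, float)
    J = Y.n_taxa
    Mu = X.values @ B
    pos = Y.values > 0
    if _is_identity(R):
        p_one = ndtr(Mu)
        p = np.where(pos, p_one, 1.0 - p_one)
        p = np.maximum(p, PROB_FLOOR)
        return -2.0 * np.log(p).sum(axis=0)
    log_joint = _site_log_probs(Y, X, B, R, mc)
    out = np.empty(J)
    for j in range(J):
        keep = [k for k in range(J) if k != j]
        sub = np.ix_(keep, keep)
        p_marg = orthant_probabilities(Mu[:, keep], R[sub], Y.values[:, keep], mc)
        p_marg = np.maximum(p_marg, PROB_FLOOR)
        out[j] = -2.0 * (log_joint - np.log(p_marg)).sum()
    return out


def _plugin_parameters(samples: PosteriorSamples):
    B = samples.mean_coefficients()
    if samples.correlations is None:
        R = np.eye(samples.n_taxa)
    else:
        R = nearest_correlation(samples.pooled_correlations().mean(axis=0))
    return B, R


def _draw_subset(samples: PosteriorSamples, max_draws: int | None):
    Bs = samples.pooled_coefficients()
    Rs = samples.pooled_correlations() if samples.correlations is not None else None
    n = Bs.shape[0]
    if max_draws is not None and n > max_draws:
        idx = np.linspace(0, n - 1, max_draws).round().astype(int)
        Bs = Bs[idx]
        Rs = Rs[idx] if Rs is not None else None
    return Bs, Rs


def dic(
    samples: PosteriorSamples,
    Y: OccurrenceMatrix,
    X: DesignMatrix,
    mc: GhkSettings = GhkSettings(),
    max_draws: int | None = None,
) -> DicResult:
    """Deviance information criterion from posterior draws.

    Dbar averages the integrated deviance over retained draws (optionally an
    evenly spaced subset of ``max_draws`` when GHK evaluation dominates
    runtime); D(theta_bar) plugs in posterior means.  DIC = 2 Dbar - D(theta_bar).
    """
    Bs, Rs = _draw_subset(samples, max_draws)
    if Bs.shape[0] < 2:
        raise DataValidationError("DIC needs at least 2 retained draws")
    eye = np.eye(samples.n_taxa)
    devs = np.empty(Bs.shape[0])
    for i in range(Bs.shape[0]):
        R_i = Rs[i] if Rs is not None else eye
        devs[i] = deviance(Y, X, Bs[i], R_i, mc)
    if not np.all(np.isfinite(devs)):
        bad = np.flatnonzero(~np.isfinite(devs)).tolist()
        raise DataValidationError(f"non-finite deviance at draws {bad}")
    B_bar, R_bar = _plugin_parameters(samples)
    d_at_mean = deviance(Y, X, B_bar, R_bar, mc)
    return DicResult(mean_deviance=float(devs.mean()), deviance_at_mean=d_at_mean)


def proportion_explained(
    model_samples: PosteriorSamples,
    null_samples: PosteriorSamples,
    Y: OccurrenceMatrix,
    X: DesignMatrix,
    mc: GhkSettings = GhkSettings(),
) -> DevianceSummary:
    """Proportion of each taxon's null deviance explained by a model.

    Both fits must be on the same occurrence data and share the design
    matrix (coefficients carry structural zeros, so one X serves all model
    variants).  Deviances are evaluated at posterior-mean parameters.
    """
    if model_samples.taxon_names != null_samples.taxon_names:
        raise DataValidationError("fits are not on the same taxa")
    B0, R0 = _plugin_parameters(null_samples)
    B1, R1 = _plugin_parameters(model_samples)
    d_null = per_taxon_deviance(Y, X, B0, R0, mc)
    d_model = per_taxon_deviance(Y, X, B1, R1, mc)
    if np.any(d_null <= 0):
        raise DataValidationError("degenerate data: null deviance is zero")
    return DevianceSummary(
        taxon_names=list(Y.taxon_names),
        per_taxon_null_deviance=d_null,
        per_taxon_residual_deviance=d_model,
    )
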