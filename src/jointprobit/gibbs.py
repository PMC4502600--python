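"""Gibbs sampler for the Bayesian multivariate probit JSDM.

The model: for site row i and taxon j,

    y_ij = 1(z_ij > 0),        z_i ~ MVN(B' x_i, R),

with B the (structurally sparse) coefficient matrix and R a taxa-by-taxa
residual correlation matrix.  Each taxon's abiotic niche is a probit
regression; R soaks up co-occurrence the covariates do not explain and is the
model's proxy for biotic interaction.

Sampling uses truncated-normal latent-variable augmentation: one sweep is

    z | B, R, y   (element-wise univariate truncated normals)
    B | z, R      (conjugate seemingly-unrelated-regressions normal draw)
    R | z, B      (parameter-expanded inverse-Wishart step, skipped when the
                   variant constrains R to the identity)

The correlation step works on an expanded, non-identified covariance scale:
the chain keeps an unrestricted covariance S ~ IW(nu0 + n, I + E'E) with
nu0 = n_taxa + 1 (which induces a marginally uniform prior on each
off-diagonal correlation), and draws are normalised back to the identified
scale when stored: R = cov2cor(S), coefficients divided by sqrt(diag S).

Coefficient priors are independent Normal(0, 10^2); z = 0 is counted as
absence (a measure-zero tie, fixed for determinism).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri

from .datatypes import (
    ConvergenceWarning,
    DataValidationError,
    DesignMatrix,
    McmcSettings,
    ModelSpec,
    OccurrenceMatrix,
    PosteriorSamples,
    QuasiSeparationWarning,
    validate_correlation_matrix,
)

__all__ = [
    "sample_latent",
    "sample_coefficients",
    "sample_correlation",
    "fit",
    "split_rhat",
]

#: default prior standard deviation for each free regression coefficient
PRIOR_COEF_SD = 10.0

_TINY = 1e-15


def _truncated_normal(mean, sd, positive, u):
    """Inverse-CDF draw of N(mean, sd) truncated to (0, inf) where
    ``positive`` else (-inf, 0].  ``u`` are uniforms on (0, 1)."""
    a = ndtr(-mean / sd)  # P(N(mean, sd) <= 0)
    # probability mass of the allowed half-line, then invert
    p = np.where(positive, a + u * (1.0 - a), u * a)
    p = np.clip(p, _TINY, 1.0 - _TINY)
    z = mean + sd * ndtri(p)
    # guard the sign constraint against rounding in extreme tails
    return np.where(positive, np.maximum(z, 1e-12), np.minimum(z, 0.0))


def _latent_sweep(Z, Y_pos, M, Omega, rng):
    """One in-place Gibbs sweep over latent columns (taxa in index order).

    Z, M are (n, J); Omega is the precision of the row covariance.  The full
    conditional of z_ij given the rest of row i is univariate normal with
    variance 1/Omega_jj, truncated by the observed occurrence.
    """
    n, J = Z.shape
    Zc = Z - M
    for j in range(J):
        om_jj = Omega[j, j]
        r = Zc @ Omega[:, j] - om_jj * Zc[:, j]
        cond_mean = M[:, j] - r / om_jj
        cond_sd = 1.0 / np.sqrt(om_jj)
        u = rng.random(n)
        Z[:, j] = _truncated_normal(cond_mean, cond_sd, Y_pos[:, j], u)
        Zc[:, j] = Z[:, j] - M[:, j]
    return Z


def sample_latent(Y, X, B, R, rng, z_init=None):
    """Draw the latent matrix z from its full conditionals given (B, R).

    Each element is a univariate truncated normal: the conditional of
    MVN(x_i B, R) on the other entries of row i, truncated to (0, inf) if the
    taxon was present, (-inf, 0] otherwise.  Taxa are swept in index order.
    """
    Yv = Y.values if isinstance(Y, OccurrenceMatrix) else np.asarray(Y, float)
    Xv = X.values if isinstance(X, DesignMatrix) else np.asarray(X, float)
    B = np.asarray(B, float)
    R = validate_correlation_matrix(R)
    if Xv.shape[0] != Yv.shape[0] or B.shape != (Xv.shape[1], Yv.shape[1]) or R.shape[0] != Yv.shape[1]:
        raise DataValidationError("dimension mismatch between Y, X, B, R")
    Omega = np.linalg.inv(R)
    M = Xv @ B
    if z_init is None:
        Z = np.where(Yv > 0, 0.5, -0.5) + 0.0 * M
    else:
        Z = np.array(z_init, dtype=float, copy=True)
    return _latent_sweep(Z, Yv > 0, M, Omega, rng)


class _CoefficientUpdater:
    """Caches the per-taxon design slices and cross-Gram blocks so the
    conjugate SUR draw costs one Cholesky per iteration."""

    def __init__(self, X: np.ndarray, mask: np.ndarray, prior_precision: float):
        self.X = X
        self.mask = mask
        self.idx = [np.flatnonzero(mask[:, j]) for j in range(mask.shape[1])]
        self.sizes = [len(ix) for ix in self.idx]
        self.offsets = np.concatenate([[0], np.cumsum(self.sizes)])
        self.p_total = int(self.offsets[-1])
        self.prior_precision = prior_precision
        # G[j][k] = X_j' X_k restricted to each taxon's columns
        self.G = [
            [X[:, self.idx[j]].T @ X[:, self.idx[k]] for k in range(mask.shape[1])]
            for j in range(mask.shape[1])
        ]
        self.Xs = [X[:, ix] for ix in self.idx]

    def draw(self, Z: np.ndarray, Omega: np.ndarray, rng) -> np.ndarray:
        J = self.mask.shape[1]
        P = np.zeros((self.p_total, self.p_total))
        rhs = np.zeros(self.p_total)
        ZOm = Z @ Omega
        for j in range(J):
            s0, s1 = self.offsets[j], self.offsets[j + 1]
            rhs[s0:s1] = self.Xs[j].T @ ZOm[:, j]
            for k in range(j, J):
                t0, t1 = self.offsets[k], self.offsets[k + 1]
                block = Omega[j, k] * self.G[j][k]
                P[s0:s1, t0:t1] = block
                if k != j:
                    P[t0:t1, s0:s1] = block.T
        P[np.diag_indices_from(P)] += self.prior_precision
        try:
            c, low = cho_factor(P, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank checks
            raise DataValidationError(f"singular coefficient precision: {exc}")
        mean = cho_solve((c, low), rhs)
        noise = solve_triangular(c.T if low else c, rng.standard_normal(self.p_total), lower=False)
        beta = mean + noise
        B = np.zeros(self.mask.shape)
        for j in range(J):
            B[self.idx[j], j] = beta[self.offsets[j]: self.offsets[j + 1]]
        return B


def sample_coefficients(Z, X, R, prior_precision, rng, spec=None, taxon_names=None):
    """Draw the coefficient matrix from its multivariate normal full
    conditional given (z, X, R) under independent Normal(0, 1/prior_precision)
    priors.  Structural zeros of the model spec are preserved.

    ``prior_precision = np.inf`` is the degenerate point-mass-at-zero prior
    and returns an all-zero matrix; ``prior_precision = 0`` is the improper
    flat prior whose conditional mean is the GLS solution.
    """
    Z = np.asarray(Z, float)
    Xv = X.values if isinstance(X, DesignMatrix) else np.asarray(X, float)
    R = validate_correlation_matrix(R)
    n, J = Z.shape
    K = Xv.shape[1]
    if spec is None:
        mask = np.ones((K, J), dtype=bool)
    else:
        if taxon_names is None:
            raise ValueError("taxon_names required when a ModelSpec is given")
        mask = spec.coefficient_mask(X, taxon_names)
    if np.isinf(prior_precision):
        return np.zeros((K, J))
    for j in range(J):
        Xj = Xv[:, mask[:, j]]
        if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
            name = taxon_names[j] if taxon_names is not None else f"taxon {j}"
            raise DataValidationError(f"rank-deficient design for {name}")
    upd = _CoefficientUpdater(Xv, mask, prior_precision)
    return upd.draw(Z, np.linalg.inv(R), rng)


def _sample_inverse_wishart(df: float, scale: np.ndarray, rng):
    """Bartlett-decomposition draw of S ~ InverseWishart(df, scale).

    Returns (S, S_inv); the inverse comes free and feeds the next latent
    sweep.  S_inv ~ Wishart(df, scale^{-1}).
    """
    J = scale.shape[0]
    L_scale = np.linalg.cholesky(scale)
    Linv = solve_triangular(L_scale, np.eye(J), lower=True)
    # lower-triangular Bartlett factor
    A = np.zeros((J, J))
    A[np.diag_indices(J)] = np.sqrt(rng.chisquare(df - np.arange(J)))
    A[np.tril_indices(J, -1)] = rng.standard_normal(J * (J - 1) // 2)
    # W = (T A)(T A)' ~ Wishart(df, scale^{-1}) with T = chol(scale^{-1})
    L_inv = np.linalg.cholesky(Linv.T @ Linv)
    LA = L_inv @ A
    S_inv = LA @ LA.T
    inv_LA = solve_triangular(LA, np.eye(J), lower=True)
    S = inv_LA.T @ inv_LA
    return S, S_inv


def sample_correlation(E, rng, prior_df_offset: int | None = None):
    """Parameter-expanded draw of the residual correlation matrix.

    Given latent residuals E = z - XB (n, J), samples an unconstrained
    covariance S ~ IW(J + 1 + n, I + E'E) and rescales it to the correlation
    scale.  The IW(J+1, I) prior on the expanded covariance induces a
    marginally uniform prior on each off-diagonal correlation.

    Returns (R, d) where d = sqrt(diag S) is the latent rescaling that maps
    expanded-scale coefficients/latents back to the identified scale.
    """
    E = np.asarray(E, float)
    if not np.all(np.isfinite(E)):
        raise DataValidationError("residuals must be finite")
    n, J = E.shape
    if J == 1:
        return np.ones((1, 1)), np.ones(1)
    nu0 = (J + 1) if prior_df_offset is None else prior_df_offset
    df = nu0 + n
    if df <= J - 1:
        raise DataValidationError(
            f"improper correlation posterior: {n} rows cannot support {J} taxa "
            "under the chosen prior"
        )
    S, _ = _sample_inverse_wishart(df, np.eye(J) + E.T @ E, rng)
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    R = 0.5 * (R + R.T)
    np.fill_diagonal(R, 1.0)
    return R, d


def split_rhat(draws: np.ndarray) -> float:
    """Split potential-scale-reduction statistic for one scalar parameter,
    from an (n_chains, n_draws) array."""
    import arviz as az

    draws = np.asarray(draws, float)
    if draws.shape[1] < 4 or np.allclose(draws.std(), 0.0):
        return 1.0
    return float(az.rhat(az.convert_to_dataset(draws))["x"].values)


def _split_rhat_numpy(draws: np.ndarray) -> float:
    """Vectorised split-Rhat (rank-free classic form) used in the fit loop."""
    m, n = draws.shape
    half = n // 2
    if half < 2:
        return np.nan
    chains = np.concatenate([draws[:, :half], draws[:, half: 2 * half]], axis=0)
    cm = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    if w <= 1e-300:
        return 1.0
    b = half * cm.var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def fit(
    Y: OccurrenceMatrix,
    X: DesignMatrix,
    spec: ModelSpec,
    settings: McmcSettings,
    check_convergence: bool = True,
) -> PosteriorSamples:
    """Fit the multivariate probit JSDM by Gibbs sampling.

    Runs ``settings.n_chains`` independent chains (chain index folded into the
    seeded stream), each cycling latent | rest, B | rest, R | rest — the
    correlation step is skipped for the identity-constrained ``null`` and
    ``environment_only`` variants.  Returns thinned post-burn-in draws on the
    identified correlation scale.  Deterministic given the seed.
    """
    if Y.n_sites != X.n_sites:
        raise DataValidationError("occurrence and design matrices are not row-aligned")
    prev = Y.prevalence()
    degenerate = [t for t, p in zip(Y.taxon_names, prev) if p in (0.0, 1.0)]
    if degenerate:
        warnings.warn(
            f"taxa observed everywhere or nowhere: {degenerate}; quasi-separation "
            "risk, the proper coefficient prior regularises the fit",
            QuasiSeparationWarning,
        )
    mask = spec.coefficient_mask(X, Y.taxon_names)
    n, J = Y.values.shape
    K = X.n_covariates
    kept = settings.n_kept_per_chain
    estimate_R = spec.estimates_correlation

    updater = _CoefficientUpdater(X.values, mask, 1.0 / PRIOR_COEF_SD**2)
    for j in range(J):
        Xj = X.values[:, mask[:, j]]
        if np.linalg.matrix_rank(Xj) < Xj.shape[1]:
            raise DataValidationError(f"rank-deficient design for taxon {Y.taxon_names[j]!r}")

    coef_draws = np.empty((settings.n_chains, kept, K, J))
    corr_draws = np.empty((settings.n_chains, kept, J, J)) if estimate_R else None

    ss = np.random.SeedSequence(settings.seed)
    child_seeds = ss.spawn(settings.n_chains)
    Y_pos = Y.values > 0
    eye = np.eye(J)
    nu0 = J + 1

    for chain, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        B = np.zeros((K, J))
        Sigma = eye.copy()
        Omega = eye.copy()
        Z = np.where(Y_pos, 0.5, -0.5).astype(float)
        keep_at = settings.n_burnin + settings.thin - 1
        k_out = 0
        for it in range(settings.n_iterations):
            M = X.values @ B
            _latent_sweep(Z, Y_pos, M, Omega, rng)
            B = updater.draw(Z, Omega, rng)
            if estimate_R:
                E = Z - X.values @ B
                Sigma, Omega = _sample_inverse_wishart(nu0 + n, eye + E.T @ E, rng)
            if it == keep_at:
                keep_at += settings.thin
                if estimate_R:
                    d = np.sqrt(np.diag(Sigma))
                    coef_draws[chain, k_out] = B / d[None, :]
                    Rdraw = Sigma / np.outer(d, d)
                    Rdraw = 0.5 * (Rdraw + Rdraw.T)
                    np.fill_diagonal(Rdraw, 1.0)
                    corr_draws[chain, k_out] = Rdraw
                else:
                    coef_draws[chain, k_out] = B
                k_out += 1
        assert k_out == kept

    rhat: dict[str, float] = {}
    if check_convergence and kept >= 4:
        for kk in range(K):
            for j in range(J):
                if mask[kk, j]:
                    rhat[f"beta[{X.covariate_names[kk]},{Y.taxon_names[j]}]"] = _split_rhat_numpy(
                        coef_draws[:, :, kk, j]
                    )
        if estimate_R:
            for a in range(J):
                for b in range(a + 1, J):
                    rhat[f"R[{Y.taxon_names[a]},{Y.taxon_names[b]}]"] = _split_rhat_numpy(
                        corr_draws[:, :, a, b]
                    )

    samples = PosteriorSamples(
        coefficients=coef_draws,
        correlations=corr_draws,
        model_spec=spec,
        settings=settings,
        covariate_names=list(X.covariate_names),
        taxon_names=list(Y.taxon_names),
        rhat=rhat,
    )
    if check_convergence and kept >= 4:
        samples.warn_if_unconverged()
    return samples
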