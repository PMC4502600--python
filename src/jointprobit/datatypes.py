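"""Core data containers for the multivariate probit JSDM.

The model works on a site-by-taxon binary occurrence matrix Y and a shared
site-by-covariate design matrix X.  Per-taxon regression coefficients live in
a single covariates-by-taxa matrix B whose structural zeros encode which
covariates each taxon's niche model uses; the residual correlation matrix R
(taxa-by-taxa, unit diagonal) carries the between-taxon association that the
environmental terms do not explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

ModelType = Literal["null", "community_only", "environment_only", "full"]

#: model variants in which the residual correlation matrix is estimated
#: rather than fixed to the identity
CORRELATED_MODELS = ("community_only", "full")

CovariateKind = Literal["intercept", "continuous", "binary", "forced_dummy"]


class DataValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass
class OccurrenceMatrix:
    """Binary presence/absence records, one row per surveyed site visit."""

    values: np.ndarray
    site_ids: list[str]
    taxon_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.site_ids = [str(s) for s in self.site_ids]
        self.taxon_names = [str(t) for t in self.taxon_names]
        if self.values.ndim != 2:
            raise DataValidationError("occurrence values must be 2-D")
        n, j = self.values.shape
        if n < 2 or j < 1:
            raise DataValidationError("need at least 2 sites and 1 taxon")
        if len(self.site_ids) != n or len(self.taxon_names) != j:
            raise DataValidationError("label lengths do not match value shape")
        if len(set(self.site_ids)) != n:
            raise DataValidationError("site_ids are not unique")
        if len(set(self.taxon_names)) != j:
            raise DataValidationError("taxon_names are not unique")
        bad = ~np.isin(self.values, (0.0, 1.0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise DataValidationError(
                f"non-binary occurrence value {self.values[r, c]!r} at "
                f"site {self.site_ids[r]!r}, taxon {self.taxon_names[c]!r}"
            )

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def prevalence(self) -> np.ndarray:
        """Fraction of sites occupied, per taxon."""
        return self.values.mean(axis=0)


@dataclass
class DesignMatrix:
    """Shared numeric design matrix: intercept first, continuous columns
    standardised to mean 0 / sample sd 1 over the analysed rows, binary and
    forced dummy columns in {0, 1}."""

    values: np.ndarray
    covariate_names: list[str]
    covariate_kinds: list[CovariateKind]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.covariate_names = [str(c) for c in self.covariate_names]
        if self.values.ndim != 2:
            raise DataValidationError("design values must be 2-D")
        n, k = self.values.shape
        if len(self.covariate_names) != k or len(self.covariate_kinds) != k:
            raise DataValidationError("covariate labels do not match shape")
        if len(set(self.covariate_names)) != k:
            raise DataValidationError("covariate names are not unique")
        if self.covariate_kinds[0] != "intercept" or not np.all(self.values[:, 0] == 1.0):
            raise DataValidationError("first column must be an all-ones intercept")
        for idx, kind in enumerate(self.covariate_kinds):
            col = self.values[:, idx]
            if kind == "continuous":
                if n > 1 and (abs(col.mean()) > 1e-8 or abs(col.std(ddof=1) - 1.0) > 1e-6):
                    raise DataValidationError(
                        f"continuous covariate {self.covariate_names[idx]!r} is "
                        "not standardised (mean 0, sample sd 1)"
                    )
            elif kind in ("binary", "forced_dummy"):
                if not np.all(np.isin(col, (0.0, 1.0))):
                    raise DataValidationError(
                        f"{kind} covariate {self.covariate_names[idx]!r} has "
                        "values outside {0, 1}"
                    )
        if np.linalg.matrix_rank(self.values) < k:
            raise DataValidationError("design matrix is rank deficient")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def column_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.covariate_names)}
        missing = [c for c in names if c not in lookup]
        if missing:
            raise KeyError(f"unknown covariates: {missing}")
        return np.array([lookup[c] for c in names], dtype=int)


@dataclass
class ModelSpec:
    """Which covariates enter each taxon's niche model, and the model variant.

    ``null`` and ``community_only`` use only the intercept and the forced
    round/area dummies; ``environment_only`` and ``full`` add each taxon's
    selected environmental covariates.  ``community_only`` and ``full``
    estimate the residual correlation matrix; the other two fix it to the
    identity.
    """

    model_type: ModelType
    per_taxon_covariates: dict[str, list[str]] = field(default_factory=dict)
    forced_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model_type not in ("null", "community_only", "environment_only", "full"):
            raise DataValidationError(f"unknown model_type {self.model_type!r}")
        if self.model_type in ("null", "community_only"):
            nonempty = {t: c for t, c in self.per_taxon_covariates.items() if c}
            if nonempty:
                raise DataValidationError(
                    f"{self.model_type} models take no environmental covariates "
                    f"(got {sorted(nonempty)})"
                )
        overlap = {
            t for t, c in self.per_taxon_covariates.items() if set(c) & set(self.forced_terms)
        }
        if overlap:
            raise DataValidationError(
                f"per-taxon covariates overlap forced terms for taxa {sorted(overlap)}"
            )

    @property
    def estimates_correlation(self) -> bool:
        return self.model_type in CORRELATED_MODELS

    def covariates_for(self, taxon: str) -> list[str]:
        """Full ordered covariate list for one taxon: intercept, forced
        terms, then (for environment-aware variants) its selected subset."""
        cols = ["intercept"] + list(self.forced_terms)
        if self.model_type in ("environment_only", "full"):
            cols += list(self.per_taxon_covariates.get(taxon, []))
        return cols

    def coefficient_mask(self, X: DesignMatrix, taxon_names: Sequence[str]) -> np.ndarray:
        """Boolean (n_covariates, n_taxa) mask of free coefficients."""
        mask = np.zeros((X.n_covariates, len(taxon_names)), dtype=bool)
        for j, taxon in enumerate(taxon_names):
            mask[X.column_indices(self.covariates_for(taxon)), j] = True
        return mask

    def to_dict(self) -> dict:
        return {
            "model_type": self.model_type,
            "per_taxon_covariates": {t: list(c) for t, c in self.per_taxon_covariates.items()},
            "forced_terms": list(self.forced_terms),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            model_type=d["model_type"],
            per_taxon_covariates={t: list(c) for t, c in d.get("per_taxon_covariates", {}).items()},
            forced_terms=list(d.get("forced_terms", [])),
        )


def validate_correlation_matrix(R: np.ndarray, *, atol: float = 1e-8) -> np.ndarray:
    """Check symmetry, unit diagonal and positive definiteness of R."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise DataValidationError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=atol):
        raise DataValidationError("correlation matrix is not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=atol):
        raise DataValidationError("correlation matrix diagonal is not 1")
    eigmin = np.linalg.eigvalsh(R)[0]
    if eigmin <= 0:
        raise DataValidationError(f"correlation matrix not positive definite (min eig {eigmin:g})")
    return R


@dataclass
class McmcSettings:
    """Chain configuration.  The seed must be given explicitly; one seeded
    generator drives the whole fit, with the chain index folded into the
    stream so chains are independent but jointly reproducible."""

    seed: int
    n_iterations: int = 30_000
    n_burnin: int = 10_000
    thin: int = 10
    n_chains: int = 2

    def __post_init__(self) -> None:
        if self.n_iterations <= 0 or self.n_burnin < 0 or self.thin < 1 or self.n_chains < 1:
            raise DataValidationError("MCMC settings must be positive")
        if self.n_burnin >= self.n_iterations:
            raise DataValidationError("n_burnin must be smaller than n_iterations")

    @property
    def n_kept_per_chain(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws of (B, R) plus fit metadata.

    ``coefficients`` has shape (n_chains, n_kept, n_covariates, n_taxa) on the
    identified (correlation) scale, with structural zeros where a covariate is
    excluded from a taxon's model.  ``correlations`` has shape
    (n_chains, n_kept, n_taxa, n_taxa) or is None for identity-constrained
    variants.
    """

    coefficients: np.ndarray
    correlations: np.ndarray | None
    model_spec: ModelSpec
    settings: McmcSettings
    covariate_names: list[str]
    taxon_names: list[str]
    rhat: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.settings.n_chains
        kept = self.settings.n_kept_per_chain
        if self.coefficients.shape[:2] != (c, kept):
            raise DataValidationError(
                f"expected {c} chains x {kept} kept draws, got {self.coefficients.shape[:2]}"
            )
        if self.model_spec.estimates_correlation:
            if self.correlations is None:
                raise DataValidationError("correlated model without correlation draws")
        elif self.correlations is not None:
            raise DataValidationError("identity-constrained model stores no correlation draws")

    @property
    def n_taxa(self) -> int:
        return self.coefficients.shape[3]

    @property
    def n_draws(self) -> int:
        return self.coefficients.shape[0] * self.coefficients.shape[1]

    def pooled_coefficients(self) -> np.ndarray:
        """(n_draws, n_covariates, n_taxa) with chains stacked."""
        return self.coefficients.reshape((-1,) + self.coefficients.shape[2:])

    def pooled_correlations(self) -> np.ndarray:
        if self.correlations is None:
            raise ValueError("no correlations were estimated for this model")
        return self.correlations.reshape((-1,) + self.correlations.shape[2:])

    def mean_coefficients(self) -> np.ndarray:
        return self.pooled_coefficients().mean(axis=0)

    def mean_correlation(self) -> np.ndarray:
        """Element-wise posterior mean of R, projected to the nearest valid
        correlation matrix (the mean of correlation matrices need not be one)."""
        if self.correlations is None:
            return np.eye(self.n_taxa)
        return nearest_correlation(self.pooled_correlations().mean(axis=0))

    def warn_if_unconverged(self, threshold: float = 1.1) -> list[str]:
        flagged = [k for k, v in self.rhat.items() if np.isfinite(v) and v > threshold]
        if flagged:
            warnings.warn(
                f"split-Rhat above {threshold} for {len(flagged)} parameter(s): "
                f"{flagged[:5]}{'...' if len(flagged) > 5 else ''}",
                ConvergenceWarning,
            )
        return flagged


class ConvergenceWarning(UserWarning):
    """Emitted when the split potential-scale-reduction check fails."""


class QuasiSeparationWarning(UserWarning):
    """Emitted for taxa observed everywhere or nowhere (intercept weakly
    identified; the proper prior regularises the fit)."""


def nearest_correlation(A: np.ndarray, *, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a nearby valid correlation matrix by
    flooring eigenvalues at ``eig_floor`` and rescaling to unit diagonal."""
    A = 0.5 * (A + A.T)
    w, V = np.linalg.eigh(A)
    w = np.maximum(w, eig_floor)
    B = (V * w) @ V.T
    d = np.sqrt(np.diag(B))
    R = B / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R
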