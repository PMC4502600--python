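"""Forward stepwise AIC covariate selection with maximum-likelihood probit fits.

Run separately for each taxon before the joint model is fitted: starting from
a model with the intercept and the forced round/area dummies, candidates are
added one at a time, always taking the single candidate with the largest AIC
decrease, until no candidate lowers AIC.  Forced terms are never dropped and
never compete with candidates.  The procedure is fully deterministic; ties in
AIC improvement (to machine precision) are broken by the user-supplied
candidate ordering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .datatypes import DataValidationError, DesignMatrix

__all__ = ["SelectionError", "SeparationError", "SelectionResult", "probit_mle", "aic", "forward_stepwise"]

logger = logging.getLogger(__name__)

#: two AIC values within this are treated as equal for tie-breaking
_AIC_TIE_TOL = 1e-9


class SelectionError(ValueError):
    pass


class SeparationError(SelectionError):
    """Perfect separation: the probit MLE does not exist."""


@dataclass
class SelectionResult:
    taxon: str
    selected_covariates: list[str]
    aic_trace: list[float]
    forced_terms: list[str]
    final_aic: float = field(init=False)

    def __post_init__(self) -> None:
        diffs = np.diff(self.aic_trace)
        if np.any(diffs >= 0):
            raise DataValidationError("AIC trace must be strictly decreasing")
        if set(self.selected_covariates) & set(self.forced_terms):
            raise DataValidationError("selected covariates overlap forced terms")
        self.final_aic = self.aic_trace[-1]


def probit_mle(y: np.ndarray, X) -> tuple[np.ndarray, float]:
    """Maximum-likelihood probit fit; returns (coefficients, log-likelihood).

    The likelihood is Bernoulli with success probability Phi(x . beta).
    Raises :class:`SeparationError` when the data are perfectly separated.
    """
    y = np.asarray(y, float)
    Xv = X.values if isinstance(X, DesignMatrix) else np.asarray(X, float)
    names = X.covariate_names if isinstance(X, DesignMatrix) else [f"x{i}" for i in range(Xv.shape[1])]
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise SelectionError(f"rank-deficient design over covariates {names}")
    intercept_only = Xv.shape[1] == 1 and np.all(Xv == 1.0)
    if (y.min() == y.max()) and not intercept_only:
        raise SeparationError(f"constant response with covariates {names}")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Probit(y, Xv).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"perfect separation with covariates {names}") from exc
        except np.linalg.LinAlgError as exc:
            # singular Hessian: numerically separated / unidentified fit
            raise SeparationError(f"degenerate probit fit with covariates {names}") from exc
    if not res.mle_retvals.get("converged", True) or np.max(np.abs(res.params)) > 1e3:
        raise SeparationError(f"probit MLE diverged with covariates {names}")
    return np.asarray(res.params, float), float(res.llf)


def aic(log_likelihood: float, k: int) -> float:
    """Akaike Information Criterion, -2 logL + 2k."""
    if k < 1:
        raise SelectionError("k must be at least 1")
    return -2.0 * log_likelihood + 2.0 * k


def forward_stepwise(
    y: np.ndarray,
    candidates: list[str],
    forced: list[str],
    data: DesignMatrix,
    taxon: str = "taxon",
) -> SelectionResult:
    """Forward stepwise AIC selection over ``candidates`` for one taxon.

    Any strictly positive AIC decrease accepts a step; a candidate whose fit
    is perfectly separated is skipped for that step with a logged warning.
    """
    if set(candidates) & set(forced):
        raise SelectionError("candidates and forced terms overlap")
    y = np.asarray(y, float)
    base_cols = ["intercept"] + list(forced)
    Xb = data.values[:, data.column_indices(base_cols)]
    _, llf = probit_mle(y, Xb)
    current_aic = aic(llf, Xb.shape[1])
    selected: list[str] = []
    trace = [current_aic]
    remaining = list(candidates)
    while remaining:
        best_name, best_aic = None, current_aic
        for name in remaining:
            cols = base_cols + selected + [name]
            Xc = data.values[:, data.column_indices(cols)]
            try:
                _, llf = probit_mle(y, Xc)
            except SeparationError:
                logger.warning("taxon %s: candidate %s skipped (perfect separation)", taxon, name)
                continue
            except SelectionError:
                logger.warning("taxon %s: candidate %s skipped (degenerate design)", taxon, name)
                continue
            cand_aic = aic(llf, Xc.shape[1])
            if cand_aic < best_aic - _AIC_TIE_TOL:
                best_name, best_aic = name, cand_aic
        if best_name is None:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        current_aic = best_aic
        trace.append(current_aic)
    return SelectionResult(
        taxon=taxon, selected_covariates=selected, aic_trace=trace, forced_terms=list(forced)
    )
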