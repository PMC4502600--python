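"""Spatial autocorrelation diagnostics for model residuals.

Raw residuals (observed occurrence minus posterior-mean probability of
presence) are split by survey round and area, screened with a Moran's I test
for spatial independence, and any flagged set is inspected with a bootstrap
spline correlogram.  "Coherent" spatial autocorrelation is operationalised as
at least three consecutive correlogram grid points whose 95% bootstrap
intervals exclude zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.spatial.distance import pdist, squareform
from scipy.special import ndtr

from .datatypes import DataValidationError, DesignMatrix, PosteriorSamples

__all__ = [
    "ResidualSet",
    "MoranResult",
    "CorrelogramResult",
    "predicted_presence",
    "raw_residuals",
    "split_residuals",
    "morans_i",
    "correlogram",
    "screen_residuals",
]


@dataclass
class ResidualSet:
    """Per-taxon raw residuals at georeferenced sites (planar metres)."""

    coords: np.ndarray              # (n, 2)
    residuals: np.ndarray           # (n, n_taxa), in [-1, 1]
    rounds: np.ndarray              # (n,) labels
    areas: np.ndarray               # (n,) labels
    site_ids: list[str]
    taxon_names: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        self.residuals = np.asarray(self.residuals, float)
        if not np.all(np.isfinite(self.coords)):
            raise DataValidationError("coordinates must be finite")
        if np.any(np.abs(self.residuals) > 1.0 + 1e-9):
            raise DataValidationError("raw residuals must lie in [-1, 1]")
        self.rounds = np.asarray(self.rounds)
        self.areas = np.asarray(self.areas)

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]


@dataclass
class MoranResult:
    statistic: float
    expected: float
    variance: float
    p_value: float
    n: int
    weights_spec: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DataValidationError("p-value outside [0, 1]")


@dataclass
class CorrelogramResult:
    distance_grid: np.ndarray
    estimate: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_boot: int
    bin_midpoints: np.ndarray = field(default_factory=lambda: np.array([]))
    bin_estimates: np.ndarray = field(default_factory=lambda: np.array([]))

    def coherent_autocorrelation(self, min_run: int = 3) -> bool:
        """True when >= min_run consecutive grid points have CIs excluding 0."""
        excludes = (self.ci_lower > 0) | (self.ci_upper < 0)
        run = best = 0
        for e in excludes:
            run = run + 1 if e else 0
            best = max(best, run)
        return best >= min_run


def predicted_presence(samples: PosteriorSamples, X: DesignMatrix) -> np.ndarray:
    """Posterior-mean marginal probability of presence, sites x taxa:
    the average over draws of Phi(x_i . beta_j)."""
    pooled = samples.pooled_coefficients()          # (draws, K, J)
    probs = ndtr(np.einsum("nk,dkj->dnj", X.values, pooled))
    return probs.mean(axis=0)


def raw_residuals(
    Y_values: np.ndarray,
    samples: PosteriorSamples,
    X: DesignMatrix,
    coords: np.ndarray,
    rounds,
    areas,
    site_ids,
) -> ResidualSet:
    """Observed occurrence minus posterior-mean predicted presence."""
    p_hat = predicted_presence(samples, X)
    return ResidualSet(
        coords=coords,
        residuals=np.asarray(Y_values, float) - p_hat,
        rounds=rounds,
        areas=areas,
        site_ids=list(site_ids),
        taxon_names=list(samples.taxon_names),
    )


def split_residuals(residuals: ResidualSet) -> dict[tuple, ResidualSet]:
    """Partition a residual set by (round, area); the splits cover the input
    exactly, one per combination present in the data."""
    if residuals.rounds.size == 0 or residuals.areas.size == 0:
        raise DataValidationError("round and area labels are required")
    out: dict[tuple, ResidualSet] = {}
    keys = list(zip(residuals.rounds.tolist(), residuals.areas.tolist()))
    for key in sorted(set(keys), key=str):
        idx = np.array([i for i, k in enumerate(keys) if k == key], dtype=int)
        out[key] = ResidualSet(
            coords=residuals.coords[idx],
            residuals=residuals.residuals[idx],
            rounds=residuals.rounds[idx],
            areas=residuals.areas[idx],
            site_ids=[residuals.site_ids[i] for i in idx],
            taxon_names=residuals.taxon_names,
        )
    return out


def _weight_matrix(coords: np.ndarray, weights_spec) -> np.ndarray:
    if isinstance(weights_spec, np.ndarray):
        W = np.asarray(weights_spec, float)
    elif weights_spec == "inverse_distance":
        d = squareform(pdist(coords))
        with np.errstate(divide="ignore"):
            W = np.where(d > 0, 1.0 / np.maximum(d, 1e-12), 0.0)
        np.fill_diagonal(W, 0.0)
    elif isinstance(weights_spec, str) and weights_spec.startswith("knn"):
        k = int(weights_spec[3:] or 4)
        d = squareform(pdist(coords))
        np.fill_diagonal(d, np.inf)
        W = np.zeros_like(d)
        nearest = np.argsort(d, axis=1)[:, :k]
        for i, row in enumerate(nearest):
            W[i, row] = 1.0
    else:
        raise DataValidationError(f"unknown weight specification {weights_spec!r}")
    if W.sum() == 0:
        raise DataValidationError("all spatial weights are zero")
    return W


def morans_i(values: np.ndarray, coords: np.ndarray, weights_spec="inverse_distance") -> MoranResult:
    """Moran's I with a two-sided normal-approximation p-value under the
    randomisation null.

    I = (n/W) * sum_ij w_ij (v_i - vbar)(v_j - vbar) / sum_i (v_i - vbar)^2.
    Default weights are inverse-distance with zero diagonal (unstandardised);
    "knn<k>" gives binary k-nearest-neighbour weights.
    """
    v = np.asarray(values, float)
    n = v.size
    if n < 3:
        raise DataValidationError("Moran's I needs at least 3 sites")
    if v.min() == v.max():
        raise DataValidationError("constant values have no spatial structure to test")
    W = _weight_matrix(np.asarray(coords, float), weights_spec)
    z = v - v.mean()
    W_sum = W.sum()
    I = (n / W_sum) * (z @ W @ z) / (z @ z)
    expected = -1.0 / (n - 1)
    # randomisation variance (uses the sample kurtosis b2)
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * W_sum**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * W_sum**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * W_sum**2
    variance = num / den - expected**2
    if variance <= 0:
        raise DataValidationError("degenerate Moran variance")
    zscore = (I - expected) / np.sqrt(variance)
    p = 2.0 * (1.0 - ndtr(abs(zscore)))
    spec_name = weights_spec if isinstance(weights_spec, str) else "custom"
    return MoranResult(
        statistic=float(I), expected=expected, variance=float(variance),
        p_value=float(min(1.0, p)), n=n, weights_spec=spec_name,
    )


def correlogram(
    values: np.ndarray,
    coords: np.ndarray,
    n_bins: int = 10,
    n_boot: int = 199,
    seed: int = 0,
    n_grid: int = 50,
) -> CorrelogramResult:
    """Distance-binned spatial correlation with a smoothing-spline curve and
    site-resampling bootstrap percentile intervals.

    Bin estimates are Moran-type: the mean over pairs in a distance bin of
    (v_i - vbar)(v_j - vbar) divided by the (biased) variance of v.  The
    reported interval at each grid point is widened, if needed, to contain
    the point-estimate curve.
    """
    v = np.asarray(values, float)
    coords = np.asarray(coords, float)
    n = v.size
    if n < 10:
        raise DataValidationError("correlogram needs at least 10 sites")
    d_full = squareform(pdist(coords))
    max_d = d_full.max()
    edges = np.linspace(0.0, max_d, n_bins + 1)
    grid = np.linspace(edges[0], max_d, n_grid)

    def curve(idx: np.ndarray):
        vv = v[idx]
        z = vv - vv.mean()
        var = (z**2).mean()
        if var == 0:
            return None
        d = d_full[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), 1)
        pd_, prod = d[iu], np.outer(z, z)[iu]
        mids, ests = [], []
        for b in range(n_bins):
            lo, hi = edges[b], edges[b + 1]
            sel = (pd_ >= lo) & (pd_ < hi) if b < n_bins - 1 else (pd_ >= lo) & (pd_ <= hi)
            if sel.sum() < 2:
                continue
            mids.append(0.5 * (lo + hi))
            ests.append(prod[sel].mean() / var)
        if len(mids) < 4:
            return None
        mids, ests = np.array(mids), np.array(ests)
        k = min(3, len(mids) - 1)
        spline = UnivariateSpline(mids, ests, k=k)
        return mids, ests, spline(grid)

    base = curve(np.arange(n))
    if base is None:
        raise DataValidationError("too few usable distance bins for a correlogram")
    mids, ests, est_curve = base
    if len(mids) < n_bins:
        warnings.warn(f"{n_bins - len(mids)} distance bin(s) dropped (fewer than 2 pairs)")

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, n_grid))
    got = 0
    attempts = 0
    while got < n_boot and attempts < 10 * n_boot:
        attempts += 1
        res = curve(rng.integers(0, n, size=n))
        if res is None:
            continue
        boot[got] = res[2]
        got += 1
    if got < n_boot:
        boot = boot[:got]
    lo = np.quantile(boot, 0.025, axis=0)
    hi = np.quantile(boot, 0.975, axis=0)
    return CorrelogramResult(
        distance_grid=grid,
        estimate=est_curve,
        ci_lower=np.minimum(lo, est_curve),
        ci_upper=np.maximum(hi, est_curve),
        n_boot=int(boot.shape[0]),
        bin_midpoints=mids,
        bin_estimates=ests,
    )


def screen_residuals(
    split_sets: dict[tuple, ResidualSet],
    alpha: float = 0.05,
    weights_spec="inverse_distance",
    n_boot: int = 199,
    seed: int = 0,
) -> list[dict]:
    """Moran screen of every (round, area, taxon) residual series, following
    flagged series (p < alpha) with a correlogram coherence check."""
    rows = []
    for key, rs in split_sets.items():
        for j, taxon in enumerate(rs.taxon_names):
            series = rs.residuals[:, j]
            entry = {"round": key[0], "area": key[1], "taxon": taxon, "n": rs.n_sites}
            try:
                mi = morans_i(series, rs.coords, weights_spec)
            except DataValidationError as exc:
                entry.update({"moran_i": np.nan, "p_value": np.nan, "flagged": False,
                              "coherent": False, "note": str(exc)})
                rows.append(entry)
                continue
            flagged = mi.p_value < alpha
            coherent = False
            if flagged and rs.n_sites >= 10:
                try:
                    cg = correlogram(series, rs.coords, n_boot=n_boot, seed=seed)
                    coherent = cg.coherent_autocorrelation()
                except DataValidationError:
                    coherent = False
            entry.update({"moran_i": mi.statistic, "p_value": mi.p_value,
                          "flagged": flagged, "coherent": coherent, "note": ""})
            rows.append(entry)
    return rows
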