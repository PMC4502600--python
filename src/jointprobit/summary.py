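"""Posterior summaries: effect sizes, Bayesian p-values, correlation networks
and co-occurrence dendrograms.

Effect sizes are the coefficients of standardised continuous covariates (so a
unit effect is one standard deviation of the covariate) and of 0/1 indicator
covariates; the two kinds are kept segregated because their scales are not
comparable.  Point estimates are maximum a posteriori (kernel-density mode),
uncertainty is the central 95% credible interval, and the "Bayesian p-value"
of a correlation is the posterior probability that it is zero or of opposite
sign to its posterior mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde

from .datatypes import DataValidationError, DesignMatrix, OccurrenceMatrix, PosteriorSamples

__all__ = [
    "standardize",
    "map_estimate",
    "credible_interval",
    "bayesian_pvalue",
    "effect_size_table",
    "correlation_network",
    "cooccurrence_dendrogram",
    "Dendrogram",
]

_MIN_DRAWS = 100


def standardize(values: np.ndarray, name: str = "covariate") -> np.ndarray:
    """Centre to mean 0 and scale to sample (n-1 denominator) sd 1."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise DataValidationError(f"{name}: need at least 2 values to standardise")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DataValidationError(f"{name}: constant covariate cannot be standardised")
    return (v - v.mean()) / sd


def map_estimate(draws: np.ndarray) -> float:
    """Posterior mode via a Gaussian KDE (Silverman bandwidth) evaluated on a
    512-point grid spanning the draw range."""
    d = np.asarray(draws, float)
    if d.size < _MIN_DRAWS:
        raise DataValidationError(f"MAP estimate needs >= {_MIN_DRAWS} draws, got {d.size}")
    lo, hi = d.min(), d.max()
    if lo == hi:
        return float(lo)
    grid = np.linspace(lo, hi, 512)
    dens = gaussian_kde(d, bw_method="silverman")(grid)
    return float(grid[np.argmax(dens)])


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Central quantile interval; quantiles use linear interpolation between
    order statistics (numpy's default rule)."""
    d = np.asarray(draws, float)
    if d.size < _MIN_DRAWS:
        raise DataValidationError(f"credible interval needs >= {_MIN_DRAWS} draws, got {d.size}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(d, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bayesian_pvalue(draws: np.ndarray) -> float:
    """Posterior probability of a zero or opposite-sign value, relative to
    the sign of the posterior mean.  0.5 when the mean is exactly zero."""
    d = np.asarray(draws, float)
    if d.size < _MIN_DRAWS:
        raise DataValidationError(f"Bayesian p-value needs >= {_MIN_DRAWS} draws, got {d.size}")
    mean = d.mean()
    if mean == 0.0:
        return 0.5
    if mean > 0:
        return float(np.mean(d <= 0))
    return float(np.mean(d >= 0))


def effect_size_table(samples: PosteriorSamples, X: DesignMatrix) -> pd.DataFrame:
    """MAP effect sizes and 95% credible intervals for every free
    (taxon, covariate) pair, tagged continuous vs discrete."""
    mask = samples.model_spec.coefficient_mask(X, samples.taxon_names)
    pooled = samples.pooled_coefficients()
    rows = []
    for k, cov in enumerate(samples.covariate_names):
        kind = X.covariate_kinds[k]
        for j, taxon in enumerate(samples.taxon_names):
            if not mask[k, j]:
                continue
            draws = pooled[:, k, j]
            lo, hi = credible_interval(draws)
            rows.append(
                {
                    "taxon": taxon,
                    "covariate": cov,
                    "map": map_estimate(draws),
                    "lo95": lo,
                    "hi95": hi,
                    "kind": "continuous" if kind == "continuous" else "discrete",
                }
            )
    return pd.DataFrame(rows)


def correlation_network(samples: PosteriorSamples, threshold: float = 0.05) -> nx.Graph:
    """Graph of taxon pairs whose residual correlation has Bayesian p-value
    below ``threshold``; edge weight is the posterior-mean correlation."""
    if samples.correlations is None:
        raise DataValidationError("no correlations were estimated for this model")
    if not (0.0 < threshold <= 1.0):
        raise DataValidationError("threshold must be in (0, 1]")
    Rs = samples.pooled_correlations()
    taxa = samples.taxon_names
    G = nx.Graph(threshold=threshold)
    G.add_nodes_from(taxa)
    J = len(taxa)
    for a in range(J):
        for b in range(a + 1, J):
            draws = Rs[:, a, b]
            p = bayesian_pvalue(draws)
            if p < threshold:
                G.add_edge(
                    taxa[a],
                    taxa[b],
                    weight=float(draws.mean()),
                    bayesian_p=p,
                    sign="positive" if draws.mean() > 0 else "negative",
                )
    return G


def network_edge_table(G: nx.Graph) -> pd.DataFrame:
    rows = [
        {"taxon_a": a, "taxon_b": b, "correlation": d["weight"], "bayesian_p": d["bayesian_p"], "sign": d["sign"]}
        for a, b, d in G.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "correlation", "bayesian_p", "sign"])


@dataclass
class Dendrogram:
    """Average-linkage merge tree over taxa on the 1 - Pearson dissimilarity
    (0 perfect positive association, 1 none, 2 perfect negative)."""

    linkage_matrix: np.ndarray
    taxon_names: list[str]
    dissimilarity: str = "one_minus_pearson"

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        root = to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.taxon_names[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(root, root.dist) + ";"


def cooccurrence_dissimilarity(Y: OccurrenceMatrix) -> np.ndarray:
    """Pairwise 1 - Pearson (phi) dissimilarity between taxon columns."""
    V = Y.values
    const = [t for t, s in zip(Y.taxon_names, V.std(axis=0)) if s == 0]
    if const:
        raise DataValidationError(f"constant taxa (cannot correlate): {const}")
    D = 1.0 - np.corrcoef(V.T)
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)


def cooccurrence_dendrogram(Y: OccurrenceMatrix, method: str = "average") -> Dendrogram:
    """Agglomerative clustering of taxa on co-occurrence dissimilarity."""
    D = cooccurrence_dissimilarity(Y)
    Z = linkage(squareform(D, checks=False), method=method)
    return Dendrogram(linkage_matrix=Z, taxon_names=list(Y.taxon_names))
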