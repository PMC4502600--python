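"""Synthetic survey-structured communities drawn from the model's own
generative process.

The generator emulates a repeated-measures larval dipping survey: a set of
dip sites in a few survey areas, visited over several rounds, with four
continuous water-chemistry covariates (depth, temperature,
oxidation-reduction potential, salinity), nine binary vegetation indicators,
and planar site coordinates inside area-specific rectangles up to 1700 m
across.  Occurrences come from the multivariate probit model itself:
z ~ MVN(XB, R) row-wise, y = 1(z > 0).

Defaults mirror the study design the package targets: 167 dip sites in
3 survey areas over 4 retained rounds, 16 taxa of which 4 are "mosquitoes",
effect sizes within +/-1.5 on the standardised scale and residual
correlations of magnitude 0.15-0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .datatypes import (
    DataValidationError,
    DesignMatrix,
    ModelSpec,
    OccurrenceMatrix,
    nearest_correlation,
    validate_correlation_matrix,
)
from .summary import standardize

__all__ = [
    "CONTINUOUS_COVARIATES",
    "VEGETATION_COVARIATES",
    "SyntheticTruth",
    "simulate_covariates",
    "simulate_community",
    "make_study_fixture",
    "make_recovery_dataset",
    "StudyFixture",
]

CONTINUOUS_COVARIATES = ["depth", "temperature", "orp", "salinity"]
VEGETATION_COVARIATES = [f"veg_{i}" for i in range(1, 10)]

#: survey-area rectangle width/height in metres (largest spans ~1700 m)
_AREA_EXTENTS = [(1700.0, 1200.0), (900.0, 700.0), (1100.0, 800.0)]


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a synthetic dataset bit-identically."""

    B_true: np.ndarray                  # (n_covariates, n_taxa)
    R_true: np.ndarray                  # (n_taxa, n_taxa)
    covariate_names: list[str]
    taxon_names: list[str]
    seed: int
    n_sites: int
    n_rounds: int
    n_areas: int

    def to_json(self) -> str:
        d = asdict(self)
        d["B_true"] = self.B_true.tolist()
        d["R_true"] = self.R_true.tolist()
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["B_true"] = np.asarray(d["B_true"], float)
        d["R_true"] = np.asarray(d["R_true"], float)
        return cls(**d)


def simulate_covariates(
    n_sites: int = 167,
    n_rounds: int = 4,
    n_areas: int = 3,
    seed: int = 0,
):
    """Simulate the survey's covariate table, coordinates and labels.

    Returns ``(covariates, coords)``: a long-format DataFrame with one row
    per site visit (site_id, round, area, 4 continuous covariates drawn from
    correlated normals then standardised over the analysed rows, 9 binary
    vegetation indicators with site-level prevalences in [0.05, 0.5]) and a
    per-visit coordinate DataFrame (site_id, x, y) in metres.
    """
    if n_sites < 2 or n_rounds < 1 or n_areas < 1:
        raise DataValidationError("sizes must be positive (and at least 2 sites)")
    rng = np.random.default_rng(seed)
    area_of_site = rng.integers(0, n_areas, size=n_sites)
    # coordinates: uniform in each area's rectangle, offset so areas are disjoint
    coords_site = np.empty((n_sites, 2))
    for a in range(n_areas):
        w, h = _AREA_EXTENTS[a % len(_AREA_EXTENTS)]
        sel = area_of_site == a
        m = int(sel.sum())
        offset = np.array([a * 10_000.0, 0.0])
        coords_site[sel] = offset + rng.random((m, 2)) * np.array([w, h])

    # correlated continuous covariates: shared site-level latent factor plus
    # round-level noise, giving realistic cross-correlation ~0.3
    n_rows = n_sites * n_rounds
    site_factor = rng.standard_normal(n_sites)
    cont = {}
    for name in CONTINUOUS_COVARIATES:
        load = 0.55
        value = (
            load * np.repeat(site_factor, n_rounds)
            + np.sqrt(1 - load**2) * rng.standard_normal(n_rows)
        )
        cont[name] = standardize(value, name)

    # binary vegetation indicators, fixed per site across rounds
    veg = {}
    for name in VEGETATION_COVARIATES:
        prevalence = rng.uniform(0.05, 0.5)
        veg[name] = np.repeat((rng.random(n_sites) < prevalence).astype(float), n_rounds)

    site_ids = [f"s{idx:04d}" for idx in range(n_sites)]
    visit_ids = [f"{s}_r{r + 1}" for s in site_ids for r in range(n_rounds)]
    table = pd.DataFrame(
        {
            "site_id": visit_ids,
            "round": [f"round{r + 1}" for _ in site_ids for r in range(n_rounds)],
            "area": [f"area{area_of_site[i] + 1}" for i in range(n_sites) for _ in range(n_rounds)],
            **cont,
            **veg,
        }
    )
    coords = pd.DataFrame(
        {
            "site_id": visit_ids,
            "x": np.repeat(coords_site[:, 0], n_rounds),
            "y": np.repeat(coords_site[:, 1], n_rounds),
        }
    )
    return table, coords


def simulate_community(
    X: DesignMatrix,
    B_true: np.ndarray,
    R_true: np.ndarray,
    seed: int,
    taxon_names: list[str] | None = None,
    site_ids: list[str] | None = None,
) -> OccurrenceMatrix:
    """Draw an occurrence matrix from the probit model: row-wise latent
    MVN(x_i B, R) draws thresholded at zero.  Deterministic given seed."""
    B_true = np.asarray(B_true, float)
    R_true = validate_correlation_matrix(R_true)
    rng = np.random.default_rng(seed)
    M = X.values @ B_true
    L = np.linalg.cholesky(R_true)
    Z = M + rng.standard_normal(M.shape) @ L.T
    J = B_true.shape[1]
    if taxon_names is None:
        taxon_names = [f"taxon_{j + 1:02d}" for j in range(J)]
    if site_ids is None:
        site_ids = [f"row{i:05d}" for i in range(X.n_sites)]
    return OccurrenceMatrix(values=(Z > 0).astype(float), site_ids=site_ids, taxon_names=taxon_names)


def build_design_from_table(table: pd.DataFrame) -> DesignMatrix:
    """Expand a covariate table (round/area categoricals, continuous and
    binary columns) into a DesignMatrix with intercept and reference-level
    round/area dummies."""
    from .io import design_from_covariates  # local import to avoid a cycle

    return design_from_covariates(table)


# -- study-scale fixture -----------------------------------------------------

_MOSQUITOES = ["mosquito_1", "mosquito_2", "mosquito_3", "mosquito_4"]
_PREDATORS = ["shrimp", "fish"]
_OTHER_TAXA = [f"fauna_{i:02d}" for i in range(1, 11)]
FIXTURE_TAXA = _MOSQUITOES + _PREDATORS + _OTHER_TAXA


@dataclass
class StudyFixture:
    occurrences: OccurrenceMatrix
    covariates: pd.DataFrame
    coords: pd.DataFrame
    design: DesignMatrix
    truth: SyntheticTruth
    model_spec: ModelSpec


def _fixture_correlation(rng: np.random.Generator, taxa: list[str]) -> np.ndarray:
    """Residual correlation with negative predator-mosquito structure.

    Both predators get negative correlations (magnitude 0.15-0.5) with two of
    the four mosquito taxa; mosquitoes correlate positively with one another;
    remaining fauna carry weak background correlation.  The target matrix is
    projected to the nearest valid correlation matrix, which preserves the
    signs of the planted entries.
    """
    J = len(taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    A = np.eye(J)
    background = rng.uniform(-0.08, 0.12, size=(J, J))
    A = A + np.triu(background, 1) + np.triu(background, 1).T
    np.fill_diagonal(A, 1.0)
    for a in range(4):
        for b in range(a + 1, 4):
            r = rng.uniform(0.2, 0.45)
            A[idx[_MOSQUITOES[a]], idx[_MOSQUITOES[b]]] = r
            A[idx[_MOSQUITOES[b]], idx[_MOSQUITOES[a]]] = r
    for p, targets in zip(_PREDATORS, (_MOSQUITOES[:2], _MOSQUITOES[2:])):
        for t in targets:
            r = -rng.uniform(0.2, 0.5)
            A[idx[p], idx[t]] = r
            A[idx[t], idx[p]] = r
    return nearest_correlation(A, eig_floor=0.05)


def make_recovery_dataset(seed: int, n_sites: int = 200, n_taxa: int = 6, n_covariates: int = 2):
    """Reduced fixture for parameter-recovery experiments.

    A single-round, single-area community of ``n_taxa`` taxa (the four
    "mosquitoes" and two "predators" when n_taxa = 6) at ``n_sites``
    independent rows with ``n_covariates`` standardised continuous
    covariates.  Coefficients and the planted correlation structure follow
    the same regime as the study-scale fixture: intercepts uniform(-1, 0),
    environmental effects of magnitude 0.4-1.5, mosquito-mosquito
    correlations +0.2..0.45 and predator-mosquito correlations -0.2..-0.5.

    Returns ``(Y, X, spec, truth)``.
    """
    ss = np.random.SeedSequence(seed)
    s_par, s_occ = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    rng = np.random.default_rng(s_par)
    taxa = (FIXTURE_TAXA[:6] if n_taxa == 6 else [f"taxon_{j + 1:02d}" for j in range(n_taxa)])
    cov_names = [f"x{i + 1}" for i in range(n_covariates)]
    cols = [np.ones(n_sites)] + [
        standardize(rng.standard_normal(n_sites), c) for c in cov_names
    ]
    X = DesignMatrix(
        values=np.column_stack(cols),
        covariate_names=["intercept"] + cov_names,
        covariate_kinds=["intercept"] + ["continuous"] * n_covariates,
    )
    B = np.zeros((1 + n_covariates, n_taxa))
    B[0] = rng.uniform(-1.0, 0.0, size=n_taxa)
    B[1:] = rng.uniform(0.4, 1.5, size=(n_covariates, n_taxa)) * rng.choice(
        [-1.0, 1.0], size=(n_covariates, n_taxa)
    )
    if n_taxa == 6:
        R = _fixture_correlation(rng, taxa)
    else:
        upper = np.triu(rng.uniform(-0.3, 0.45, size=(n_taxa, n_taxa)), 1)
        R = nearest_correlation(np.eye(n_taxa) + upper + upper.T, eig_floor=0.05)
    Y = simulate_community(X, B, R, seed=s_occ, taxon_names=taxa)
    spec = ModelSpec(
        model_type="full",
        per_taxon_covariates={t: list(cov_names) for t in taxa},
        forced_terms=[],
    )
    truth = SyntheticTruth(
        B_true=B, R_true=R, covariate_names=list(X.covariate_names), taxon_names=taxa,
        seed=seed, n_sites=n_sites, n_rounds=1, n_areas=1,
    )
    return Y, X, spec, truth


def make_study_fixture(seed: int, n_sites: int = 167, n_rounds: int = 4, n_areas: int = 3) -> StudyFixture:
    """Full synthetic dataset bundle at the study's scale: 16 taxa
    (4 mosquitoes, 2 predators with planted negative correlations, 10 other
    fauna), 167 sites x 4 rounds in 3 areas, with its generating truth."""
    ss = np.random.SeedSequence(seed)
    s_cov, s_truth, s_occ = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    covariates, coords = simulate_covariates(n_sites, n_rounds, n_areas, seed=s_cov)
    design = build_design_from_table(covariates)
    rng = np.random.default_rng(s_truth)
    taxa = list(FIXTURE_TAXA)
    J = len(taxa)
    K = design.n_covariates
    names = design.covariate_names
    B = np.zeros((K, J))
    env_names = CONTINUOUS_COVARIATES + VEGETATION_COVARIATES
    per_taxon: dict[str, list[str]] = {}
    for j, taxon in enumerate(taxa):
        B[0, j] = rng.uniform(-1.0, 0.0)  # intercepts: prevalences below 0.5
        for k, name in enumerate(names):
            kind = design.covariate_kinds[k]
            if kind == "forced_dummy":
                B[k, j] = rng.uniform(-0.4, 0.4)
        n_env = int(rng.integers(2, 5))
        chosen = list(rng.choice(env_names, size=n_env, replace=False))
        per_taxon[taxon] = chosen
        for name in chosen:
            k = names.index(name)
            magnitude = rng.uniform(0.4, 1.5)
            B[k, j] = magnitude * rng.choice([-1.0, 1.0])
    R = _fixture_correlation(rng, taxa)
    occurrences = simulate_community(
        design, B, R, seed=s_occ, taxon_names=taxa, site_ids=covariates["site_id"].tolist()
    )
    forced = [n for n, k in zip(names, design.covariate_kinds) if k == "forced_dummy"]
    truth = SyntheticTruth(
        B_true=B, R_true=R, covariate_names=list(names), taxon_names=taxa,
        seed=seed, n_sites=n_sites, n_rounds=n_rounds, n_areas=n_areas,
    )
    spec = ModelSpec(model_type="full", per_taxon_covariates=per_taxon, forced_terms=forced)
    return StudyFixture(
        occurrences=occurrences, covariates=covariates, coords=coords,
        design=design, truth=truth, model_spec=spec,
    )
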