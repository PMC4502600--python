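"""Readers and writers for survey tables, fitted models and result bundles.

CSV dialect throughout: comma-separated, UTF-8, header row required, ``.``
decimal.  Occurrence files have ``site_id`` then one 0/1 column per taxon;
covariate files have ``site_id``, categorical ``round``/``area`` columns
(dummy-expanded internally, first level as reference) and numeric covariates
(binary columns detected as such, other columns standardised).  Fits are
serialised to a directory: one delimited file per parameter block per chain
plus a JSON metadata file; result bundles carry a JSON manifest with a
content hash per file, written last so its absence flags an incomplete run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DataValidationError,
    DesignMatrix,
    McmcSettings,
    ModelSpec,
    OccurrenceMatrix,
    PosteriorSamples,
)
from .summary import standardize

__all__ = [
    "read_survey_tables",
    "design_from_covariates",
    "write_fit",
    "load_fit",
    "write_manifest",
]

logger = logging.getLogger(__name__)

_RESERVED = {"site_id", "round", "area"}
FORMAT_VERSION = "1"


def read_survey_tables(occurrence_path, covariate_path) -> tuple[OccurrenceMatrix, pd.DataFrame]:
    """Load and align the two survey CSVs on ``site_id``.

    Returns the validated occurrence matrix and the covariate table
    reordered to match it (pass the table to :func:`design_from_covariates`
    to build the design matrix).
    """
    occ = pd.read_csv(occurrence_path)
    cov = pd.read_csv(covariate_path)
    for name, df in (("occurrence", occ), ("covariate", cov)):
        if "site_id" not in df.columns:
            raise DataValidationError(f"{name} table has no site_id column")
    occ_ids = occ["site_id"].astype(str)
    cov_ids = cov["site_id"].astype(str)
    missing = sorted(set(occ_ids) ^ set(cov_ids))
    if missing:
        raise DataValidationError(f"site_ids not shared by both tables: {missing[:10]}")
    cov = cov.set_index(cov_ids).loc[occ_ids].reset_index(drop=True)
    taxa = [c for c in occ.columns if c != "site_id"]
    Y = OccurrenceMatrix(
        values=occ[taxa].to_numpy(dtype=float),
        site_ids=occ_ids.tolist(),
        taxon_names=taxa,
    )
    logger.info("loaded %d rows, %d taxa: %s", Y.n_sites, Y.n_taxa, ", ".join(taxa))
    return Y, cov


def design_from_covariates(cov: pd.DataFrame) -> DesignMatrix:
    """Build the shared design matrix from a covariate table.

    Categorical ``round`` and ``area`` columns become first-level-reference
    dummies (forced terms); {0,1}-valued numeric columns stay as binary
    indicators; everything else is standardised to mean 0 / sample sd 1.
    """
    n = len(cov)
    cols = [np.ones(n)]
    names = ["intercept"]
    kinds = ["intercept"]
    for cat in ("round", "area"):
        if cat not in cov.columns:
            continue
        levels = sorted(cov[cat].astype(str).unique())
        for level in levels[1:]:
            cols.append((cov[cat].astype(str) == level).to_numpy(float))
            names.append(f"{cat}_{level}")
            kinds.append("forced_dummy")
    for c in cov.columns:
        if c in _RESERVED:
            continue
        v = pd.to_numeric(cov[c], errors="raise").to_numpy(float)
        if set(np.unique(v)) <= {0.0, 1.0}:
            cols.append(v)
            kinds.append("binary")
        else:
            cols.append(standardize(v, c))
            kinds.append("continuous")
        names.append(c)
    return DesignMatrix(values=np.column_stack(cols), covariate_names=names, covariate_kinds=kinds)


# -- fit persistence ---------------------------------------------------------

def write_fit(samples: PosteriorSamples, out_dir) -> None:
    """Serialise a fit: per-chain coefficient and correlation draw CSVs plus
    a metadata JSON recording spec, settings and taxon/covariate labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    K = len(samples.covariate_names)
    coef_cols = [
        f"{cov}:{taxon}" for cov in samples.covariate_names for taxon in samples.taxon_names
    ]
    for c in range(samples.settings.n_chains):
        flat = samples.coefficients[c].reshape(samples.coefficients.shape[1], -1)
        pd.DataFrame(flat, columns=coef_cols).to_csv(out / f"coefficients_chain{c}.csv", index=False)
        if samples.correlations is not None:
            J = samples.n_taxa
            iu = np.triu_indices(J, 1)
            corr_cols = [
                f"{samples.taxon_names[a]}:{samples.taxon_names[b]}" for a, b in zip(*iu)
            ]
            flat_r = samples.correlations[c][:, iu[0], iu[1]]
            pd.DataFrame(flat_r, columns=corr_cols).to_csv(
                out / f"correlations_chain{c}.csv", index=False
            )
    meta = {
        "format_version": FORMAT_VERSION,
        "model_spec": samples.model_spec.to_dict(),
        "settings": {
            "seed": samples.settings.seed,
            "n_iterations": samples.settings.n_iterations,
            "n_burnin": samples.settings.n_burnin,
            "thin": samples.settings.thin,
            "n_chains": samples.settings.n_chains,
        },
        "covariate_names": samples.covariate_names,
        "taxon_names": samples.taxon_names,
        "rhat": samples.rhat,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_fit(fit_dir) -> PosteriorSamples:
    """Inverse of :func:`write_fit`."""
    d = Path(fit_dir)
    meta = json.loads((d / "metadata.json").read_text())
    settings = McmcSettings(**meta["settings"])
    spec = ModelSpec.from_dict(meta["model_spec"])
    cov_names = meta["covariate_names"]
    taxa = meta["taxon_names"]
    K, J = len(cov_names), len(taxa)
    kept = settings.n_kept_per_chain
    coefficients = np.empty((settings.n_chains, kept, K, J))
    correlations = np.empty((settings.n_chains, kept, J, J)) if spec.estimates_correlation else None
    for c in range(settings.n_chains):
        flat = pd.read_csv(d / f"coefficients_chain{c}.csv").to_numpy(float)
        coefficients[c] = flat.reshape(kept, K, J)
        if correlations is not None:
            flat_r = pd.read_csv(d / f"correlations_chain{c}.csv").to_numpy(float)
            iu = np.triu_indices(J, 1)
            for i in range(kept):
                R = np.eye(J)
                R[iu] = flat_r[i]
                R[(iu[1], iu[0])] = flat_r[i]
                correlations[c, i] = R
    return PosteriorSamples(
        coefficients=coefficients,
        correlations=correlations,
        model_spec=spec,
        settings=settings,
        covariate_names=cov_names,
        taxon_names=taxa,
        rhat=meta.get("rhat", {}),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, extra: dict | None = None) -> dict:
    """Hash every file in ``out_dir`` into ``manifest.json`` (written last:
    its absence signals an incomplete run).  Identical inputs and seeds give
    identical hashes."""
    out = Path(out_dir)
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "format_version": FORMAT_VERSION,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
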