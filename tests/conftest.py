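import numpy as np
import pytest

from jointprobit.datatypes import DesignMatrix, McmcSettings, ModelSpec
from jointprobit.simulate import simulate_community
from jointprobit.summary import standardize


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_design(n, n_continuous=2, seed=0):
    """Standardised continuous design with intercept."""
    r = np.random.default_rng(seed)
    names = ["intercept"] + [f"x{i + 1}" for i in range(n_continuous)]
    cols = [np.ones(n)] + [standardize(r.standard_normal(n)) for _ in range(n_continuous)]
    return DesignMatrix(
        values=np.column_stack(cols),
        covariate_names=names,
        covariate_kinds=["intercept"] + ["continuous"] * n_continuous,
    )


@pytest.fixture
def small_joint_data():
    """Two taxa with a known 0.5 residual correlation and known coefficients."""
    X = make_design(400, n_continuous=1, seed=3)
    B = np.array([[0.2, -0.3], [0.8, -0.6]])
    R = np.array([[1.0, 0.5], [0.5, 1.0]])
    Y = simulate_community(X, B, R, seed=7)
    spec = ModelSpec(
        model_type="full",
        per_taxon_covariates={t: ["x1"] for t in Y.taxon_names},
        forced_terms=[],
    )
    return Y, X, B, R, spec


def quick_settings(seed, iters=2000, burn=500, thin=5, chains=2):
    return McmcSettings(seed=seed, n_iterations=iters, n_burnin=burn, thin=thin, n_chains=chains)
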