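import warnings

import numpy as np
import pytest

from fabwork.cohort import generate_cohort, reduced_config
from fabwork.prep import ColumnMeta, DesignMatrix, prepare_design

warnings.filterwarnings("ignore", message=".*ArviZ.*")


def make_design(Z, y, mask=None, year=None, covariate_set="full"):
    """Hand-built design matrix for toy model tests."""
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    n, p = Z.shape
    if mask is None:
        mask = np.ones_like(Z, dtype=bool)
    if year is None:
        year = np.ones(n, dtype=np.int64)
    cols = [ColumnMeta(f"x{j}", "function", "baseline") for j in range(p)]
    return DesignMatrix(
        y=y,
        Z=np.where(mask, Z, 0.0),
        mask=mask,
        columns=cols,
        year=np.asarray(year, dtype=np.int64),
        participant=np.arange(n, dtype=np.int64),
        covariate_set=covariate_set,
    )


@pytest.fixture(scope="session")
def small_config():
    return reduced_config(150, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_design(small_panel):
    design, _ = prepare_design(small_panel, tolerance=14, covariate_set="full")
    return design


@pytest.fixture(scope="session")
def fitted_glm(small_design):
    """One modest shared GLM fit for results-level tests."""
    from fabwork.models.logistic import LogisticModelSpec, SteadyWorkLogistic

    spec = LogisticModelSpec(draws=200, warmup=200, chains=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return SteadyWorkLogistic(small_design, spec).fit(seed=11)
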