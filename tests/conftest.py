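"""Shared synthetic fixtures for the test suite.

Everything is generated programmatically with fixed seeds; no data files.
"""

import numpy as np
import pandas as pd
import pytest

from doeqtl import synthetic
from doeqtl.eqtl import covariate_design, kinship_from_probs


@pytest.fixture(scope="session")
def marker_map():
    return synthetic.make_marker_map(3, 100, 50, seed=1)


@pytest.fixture(scope="session")
def probs(marker_map):
    return synthetic.simulate_founder_mosaics(marker_map, 100, seed=2)


@pytest.fixture(scope="session")
def covariates(probs):
    return synthetic.make_covariates(probs.sample_ids, seed=3)


@pytest.fixture(scope="session")
def design(covariates):
    X, names = covariate_design(covariates)
    return X


@pytest.fixture(scope="session")
def kinship(probs):
    return kinship_from_probs(probs, loco=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def planted_module_expression(n_modules, module_size, within_r, n_samples, seed):
    """Expression with block-correlated planted modules (shared factor)."""
    rng = np.random.default_rng(seed)
    cols = {}
    a = np.sqrt(within_r)
    for m in range(n_modules):
        factor = rng.normal(size=n_samples)
        for g in range(module_size):
            cols[f"M{m}_G{g}"] = a * factor + np.sqrt(1 - a * a) * rng.normal(
                size=n_samples
            )
    return pd.DataFrame(cols)
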