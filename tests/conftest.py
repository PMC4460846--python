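import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from uvdex import SimConfig, compute_pca, generate_dataset, standardize_genes

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic dataset (seed 1) with ground truth."""
    return generate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def standardized(default_dataset):
    X, truth = default_dataset
    Xs = standardize_genes(X)
    model = compute_pca(Xs)
    return Xs, model, truth


@pytest.fixture()
def quiet():
    """Silence expected estimation warnings inside a test."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
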