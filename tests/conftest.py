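import numpy as np
import pytest

import fnirsdecode as fd


@pytest.fixture(scope="session")
def montage():
    return fd.default_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort_tables():
    """Feature tables for a small planted-effect study, shared across tests."""
    params = fd.scaled_params(4, 3, seed=7)
    return fd.simulate_feature_tables(params)


def gaussian_feature_problem(rng, n_per_class=40, n_features=8, sep=2.0,
                             informative=(0,)):
    """Synthetic trial-level feature matrix with separation on chosen columns."""
    X = rng.normal(size=(2 * n_per_class, n_features))
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    for i in informative:
        X[:n_per_class, i] += sep
    return X, y
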