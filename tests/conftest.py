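import numpy as np
import pytest

from profilereg.data import CovariateSpec, ProfileDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def binary_pair_dataset():
    """Tiny complete dataset: two binary covariates, 6 cases / 14 controls."""
    rng = np.random.default_rng(0)
    n = 20
    X = rng.integers(0, 2, size=(n, 2))
    y = np.zeros(n, dtype=int)
    y[:6] = 1
    specs = [CovariateSpec("a", "nominal", 2), CovariateSpec("b", "nominal", 2)]
    return ProfileDataset(X, y, None, specs)


def two_cluster_dataset(n=400, sep=0.9, theta=(0.3, 0.05), seed=0):
    """Well-separated two-cluster case-control data with known labels."""
    from profilereg.synthetic import SyntheticSpec, make_synthetic

    specs = [CovariateSpec("a", "nominal", 2), CovariateSpec("b", "ordinal", 3),
             CovariateSpec("c", "nominal", 2)]
    phi = [np.array([[sep, 1 - sep], [1 - sep, sep]]),
           np.array([[sep, (1 - sep) / 2, (1 - sep) / 2],
                     [(1 - sep) / 2, (1 - sep) / 2, sep]]),
           np.array([[1 - sep, sep], [sep, 1 - sep]])]
    spec = SyntheticSpec(n=n, cluster_weights=np.array([0.5, 0.5]), phi=phi,
                         theta=np.array(theta), specs=specs)
    return make_synthetic(spec, seed=seed)
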