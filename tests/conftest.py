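import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    from megnet.clinical_cohort import load_cohort

    return load_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_weight_matrix(rng, n, density=0.5, binary=False):
    """Random symmetric non-negative weight matrix with zero diagonal."""
    W = rng.uniform(0.05, 1.0, size=(n, n))
    if binary:
        W = np.ones((n, n))
    keep = rng.random((n, n)) < density
    W = W * keep
    W = np.triu(W, 1)
    return W + W.T
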