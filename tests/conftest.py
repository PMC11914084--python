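import numpy as np
import pytest
import scipy.sparse as sp

from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured synthetic dataset shared across tests."""
    from scmultistate import SimConfig, simulate_dataset

    cfg = SimConfig(n_cells=900, exact_counts=True, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_counts(rng, n_cells, n_features, density=0.3, max_count=20):
    mat = rng.integers(0, max_count, size=(n_cells, n_features))
    mask = rng.random((n_cells, n_features)) < density
    return sp.csr_matrix(mat * mask)
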