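import numpy as np
import pytest

from ctrlred import CohortSpec, generate_cohort, make_block_parcellation


@pytest.fixture(scope="session")
def demo_cohort():
    """Small shared cohort: 100 subjects, 60 parcels, 17 networks."""
    spec = CohortSpec(n_subjects=100, n_parcels=60, seed=11)
    records, connectomes = generate_cohort(spec)
    return spec, records, connectomes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_binary_adjacency(rng, n, p):
    """Symmetric 0/1 adjacency with zero diagonal."""
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, k=1)
    return a + a.T


def random_weighted_adjacency(rng, n, p=0.3, scale=50.0):
    a = random_binary_adjacency(rng, n, p)
    w = np.triu(np.rint(rng.lognormal(np.log(scale), 0.8, (n, n))), k=1)
    w = (w + w.T) * a
    return w


@pytest.fixture
def parc60():
    return make_block_parcellation(60, 17)
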