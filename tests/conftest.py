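import numpy as np
import pytest

from jsnmf import MultiOmicsDataset, RunConfig, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_blocks(rng, n=8, q=(5, 6, 4), low=0.05, high=1.0):
    return [rng.uniform(low, high, size=(n, qi)) for qi in q]


def random_factors(rng, n=8, K=3, q=(5, 6, 4)):
    W = rng.uniform(0.1, 1.0, size=(n, K))
    H = [rng.uniform(0.1, 1.0, size=(K, qi)) for qi in q]
    return W, H


@pytest.fixture
def tiny_dataset():
    """Handmade 4-sample dataset with known values."""
    sample_ids = ["s1", "s2", "s3", "s4"]
    blocks = [
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]]),
        np.array([[0.5, 0.0, 1.5], [1.0, 2.0, 0.0], [0.0, 1.0, 2.0], [2.0, 0.5, 1.0]]),
        np.array([[1.0], [0.5], [2.0], [1.5]]),
    ]
    feature_ids = [["f1", "f2"], ["g1", "g2", "g3"], ["p1"]]
    labels = np.array([0, 1, 0, 1])
    return MultiOmicsDataset(
        sample_ids=sample_ids, blocks=blocks, feature_ids=feature_ids, labels=labels
    )


@pytest.fixture
def small_cohort():
    """Small synthetic cohort with planted structure, shared across tests."""
    spec = SyntheticSpec(n=40, q=(20, 25, 30), K_true=3, module_size=6, sigma=0.1, seed=5)
    dataset, truth = generate(spec)
    return spec, dataset, truth


@pytest.fixture
def fast_config():
    return RunConfig(K=3, alpha=0.01, beta=0.01, max_iter=100, seed=5)
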