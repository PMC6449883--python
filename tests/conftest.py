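import numpy as np
import pytest

import gne


@pytest.fixture
def tiny_net() -> gne.GeneNetwork:
    """Six genes on a cycle plus one chord."""
    edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5), (1, 4)]
    return gne.GeneNetwork([f"g{i}" for i in range(6)], edges)


@pytest.fixture
def fast_hyper() -> gne.GNEHyper:
    """Small, quick configuration for training tests."""
    return gne.GNEHyper(d=16, batch_size=32, epochs=5, num_neg=5, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """60-gene, 3-module synthetic dataset, aligned and normalized."""
    cfg = gne.SyntheticConfig(
        n_genes=60, n_modules=3, p_in=0.3, p_out=0.03, n_experiments=60, seed=11
    )
    net, expr, truth = gne.generate_dataset(cfg)
    net, expr = gne.align(net, expr)
    return net, expr, truth


@pytest.fixture
def random_embeddings():
    def make(M: int, d: int, seed: int = 0) -> gne.GeneEmbeddings:
        rng = np.random.default_rng(seed)
        return gne.GeneEmbeddings([f"g{i}" for i in range(M)], rng.normal(size=(M, d)))

    return make
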