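import numpy as np
import pytest

from treeassoc.coalescent import sample_coalescent_tree


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_trees():
    """Factory: k coalescent trees on n tips from a fixed stream."""

    def make(k, n, seed=0):
        gen = np.random.default_rng(seed)
        return [sample_coalescent_tree(n, gen) for _ in range(k)]

    return make


@pytest.fixture
def balanced_phenotype():
    """Half cases, half controls, length n."""

    def make(n):
        phen = np.zeros(n, dtype=np.uint8)
        phen[: n // 2] = 1
        return phen

    return make
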