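import numpy as np
import pytest
from hypothesis import settings

import celltree as ct
from celltree import _instrument

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _reset_instrumentation():
    _instrument.reset_events()
    yield


@pytest.fixture
def toy_matrix():
    """4 cells x 3 features, integer counts, no zero rows/columns."""
    counts = np.array([
        [2, 0, 1],
        [1, 1, 0],
        [0, 3, 2],
        [4, 0, 0],
    ])
    return ct.CountMatrix(counts, ["c1", "c2", "c3", "c4"], ["g1", "g2", "g3"])


@pytest.fixture
def planted_matrix():
    m, labels = ct.simulate_block_counts(ct.BlockSpec(seed=7))
    return m, labels


@pytest.fixture
def random_tree():
    return ct.simulate_random_tree(n_leaves=8, cells_per_leaf=5, seed=3)


@pytest.fixture
def mtx_bundle(tmp_path, toy_matrix):
    ct.write_mtx_bundle(toy_matrix, tmp_path / "bundle")
    return tmp_path / "bundle"


def brute_force_modularity(weights, communities):
    """Independent oracle: Q = (1/2m) sum_ij (w_ij - k_i k_j / 2m) delta(c_i, c_j)."""
    w = np.asarray(weights, dtype=float)
    c = np.asarray(communities)
    two_m = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    for i in range(len(c)):
        for j in range(len(c)):
            if c[i] == c[j]:
                q += w[i, j] - k[i] * k[j] / two_m
    return q / two_m


@pytest.fixture
def modularity_oracle():
    return brute_force_modularity
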