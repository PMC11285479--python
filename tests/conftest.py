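import numpy as np
import pytest

from skewnet.hierarchy import AgonisticNetwork


def make_net(weights, ids=None) -> AgonisticNetwork:
    w = np.asarray(weights, dtype=int)
    if ids is None:
        ids = [f"f{i}" for i in range(w.shape[0])]
    return AgonisticNetwork(ids=list(ids), weights=w, year=2003, colony="C1",
                            group_id="C1-G1")


def random_digraph(n: int, rng: np.random.Generator, p: float = 0.4) -> np.ndarray:
    """Random binary adjacency with zero diagonal."""
    w = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(w, 0)
    return w


def reach_oracle(adj: np.ndarray) -> np.ndarray:
    """Brute-force transitive closure by repeated boolean squaring.

    Independent of the networkx-based implementation under test.
    """
    a = adj.astype(bool)
    closure = a.copy()
    for _ in range(adj.shape[0]):
        closure = closure | (closure @ a)
    np.fill_diagonal(closure, False)  # a node does not reach itself
    return closure.sum(axis=1) / (adj.shape[0] - 1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
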