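import numpy as np
import pytest

from mrdag.graph import GENOTYPE, PHENOTYPE, CausalGraph


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_correlation(rng: np.random.Generator, p: int) -> np.ndarray:
    """A well-conditioned random correlation matrix."""
    A = rng.normal(size=(p + 5, p))
    R = np.corrcoef(A, rowvar=False)
    # shrink toward identity to keep submatrices comfortably invertible
    R = 0.7 * R + 0.3 * np.eye(p)
    d = np.sqrt(np.diag(R))
    return R / np.outer(d, d)


def random_mixed_graph(rng: np.random.Generator, p: int, edge_prob: float = 0.4) -> CausalGraph:
    """A random labeled mixed graph (directed + undirected edges)."""
    labels = tuple(f"N{i+1}" for i in range(p))
    kinds = tuple(
        GENOTYPE if rng.random() < 0.3 else PHENOTYPE for _ in range(p)
    )
    amat = np.zeros((p, p), dtype=np.int8)
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() >= edge_prob:
                continue
            state = rng.integers(0, 3)
            if state == 0:
                amat[i, j] = 1
            elif state == 1:
                amat[j, i] = 1
            else:
                amat[i, j] = amat[j, i] = 1
    return CausalGraph(labels, kinds, amat)
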