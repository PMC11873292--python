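import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

from panrc.core import ClusterLabeling, ExpressionMatrix

settings.register_profile("ci", deadline=None, max_examples=30,
                          derandomize=True)
settings.load_profile("ci")


def random_matrix(rng, n_cells, n_genes, density=0.3, max_count=20):
    """Small random sparse count matrix for oracle comparisons."""
    counts = np.where(
        rng.random((n_cells, n_genes)) < density,
        rng.integers(1, max_count + 1, size=(n_cells, n_genes)),
        0,
    )
    return ExpressionMatrix(
        sp.csr_array(counts),
        [f"g{j}" for j in range(n_genes)],
        [f"c{i}" for i in range(n_cells)],
    )


def random_labeling(rng, m, n_clusters):
    """Random labeling over the matrix's cells, every cluster non-empty."""
    n = m.n_cells
    assert n >= n_clusters
    assign = np.concatenate([
        np.arange(n_clusters),
        rng.integers(0, n_clusters, size=n - n_clusters),
    ])
    rng.shuffle(assign)
    return ClusterLabeling.from_sequences(
        m.cell_ids, [f"k{a}" for a in assign]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
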