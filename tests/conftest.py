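import numpy as np
import pytest

from stableclust import ExpressionMatrix, SimulationSpec, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    values = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 3.0]])
    return ExpressionMatrix(values=values, gene_ids=["g1", "g2", "g3"],
                            cell_ids=["c1", "c2"])


@pytest.fixture(scope="session")
def sim3_separated():
    """Three well-separated simulated clusters (50 cells each, 500 genes)."""
    return simulate(SimulationSpec(n_clusters=3, cells_per_cluster=50,
                                   n_genes=500, separability=10.0, seed=7))
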