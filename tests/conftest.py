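import numpy as np
import pytest

from dlnlrr.io_preprocess import ExpressionMatrix
from dlnlrr.graph import gaussian_affinity
from dlnlrr.solver import SolverConfig
from dlnlrr.synthetic import SubspaceSpec, make_subspace_data


@pytest.fixture
def toy_counts() -> ExpressionMatrix:
    """4 genes x 3 cells of raw counts with distinct library sizes."""
    values = np.array(
        [
            [1.0, 4.0, 10.0],
            [2.0, 6.0, 10.0],
            [3.0, 4.0, 10.0],
            [4.0, 6.0, 10.0],
        ]
    )
    return ExpressionMatrix(
        values,
        gene_ids=("g1", "g2", "g3", "g4"),
        cell_ids=("c1", "c2", "c3"),
    )


@pytest.fixture
def subspace_instance():
    """Noiseless 3-subspace instance plus its affinity graph and config."""
    X, labels = make_subspace_data(SubspaceSpec(r=3, d=2, m=30, n_per=40, seed=0))
    g = gaussian_affinity(X, t=1.0)
    cfg = SolverConfig(r=3, seed=0)
    return X, labels, g, cfg


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
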