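"""End-to-end convenience pipeline: preprocess counts, build the cell
graph, run the solver and assign labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import ClusteringResult, cluster
from .graph import AffinityGraph, gaussian_affinity
from .io_preprocess import ExpressionMatrix, preprocess
from .solver import SolverConfig, SolverState, fit


@dataclass(frozen=True)
class PipelineResult:
    X: ExpressionMatrix
    graph: AffinityGraph
    state: SolverState
    clustering: ClusteringResult

    @property
    def labels(self) -> np.ndarray:
        return self.clustering.labels


def run_pipeline(
    X: ExpressionMatrix,
    config: SolverConfig,
    min_cells_exclusive: int = 2,
    normalize: bool = True,
    log: bool = True,
    knn: int | None = None,
    kernel_width: float = 1.0,
) -> PipelineResult:
    """Raw counts in, hard cluster labels out.

    Applies gene filtering, median normalization and log10(x+1); builds
    the kNN Gaussian affinity graph on the preprocessed matrix; fits
    the low-rank model against the graph Laplacian; labels each cell by
    the argmax of its column of H.
    """
    Xp = preprocess(X, min_cells_exclusive=min_cells_exclusive, normalize=normalize, log=log)
    g = gaussian_affinity(Xp, k=knn, t=kernel_width)
    state = fit(Xp, g.L, config)
    return PipelineResult(X=Xp, graph=g, state=state, clustering=cluster(state))
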