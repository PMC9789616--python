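"""k-nearest-neighbour Gaussian affinity graph over cells and its Laplacian.

The manifold regulariser penalises ``tr(H L H^T) = 1/2 * sum_ij s_ij *
||h_i - h_j||^2``, which keeps cells that are close in expression space
close in the learned low-rank coordinates.  The affinity is

    s_ij = exp(-||x_i - x_j||^2 / (2 t^2))   if i in kNN(j) or j in kNN(i)
    s_ij = 0                                  otherwise,

with Euclidean distances over genes and an OR symmetrisation of the kNN
relation, so S is symmetric by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io_preprocess import ExpressionMatrix


def _as_cells_matrix(X) -> np.ndarray:
    """Columns-as-cells array from an ExpressionMatrix or a plain array."""
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def default_knn(n_cells: int) -> int:
    """Heuristic neighbour count: max(4, round(sqrt(n))), capped below n."""
    return min(max(4, int(round(np.sqrt(n_cells)))), n_cells - 1)


@dataclass(frozen=True)
class AffinityGraph:
    """Symmetric affinity S, degree matrix D and Laplacian L = D - S."""

    S: np.ndarray
    D: np.ndarray
    L: np.ndarray
    k: int
    t: float

    @property
    def n_cells(self) -> int:
        return self.S.shape[0]


def knn_sets(X, k: int) -> list[np.ndarray]:
    """Indices of the k nearest cells (Euclidean, excluding self) per cell."""
    V = _as_cells_matrix(X)
    n = V.shape[1]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells={n}, got {k}")
    nn = NearestNeighbors(n_neighbors=k + 1, metric="euclidean").fit(V.T)
    _, idx = nn.kneighbors(V.T)
    out = []
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k]
        # all-duplicate neighbourhoods can return k+1 non-self candidates
        out.append(np.asarray(neigh[:k], dtype=int))
    return out


def laplacian(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Degree matrix and combinatorial Laplacian of a symmetric affinity."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if S.size and S.min() < 0:
        raise ValueError("S must be non-negative")
    D = np.diag(S.sum(axis=1))
    return D, D - S


def gaussian_affinity(X, k: int | None = None, t: float = 1.0) -> AffinityGraph:
    """Gaussian-kernel affinity restricted to the OR-symmetrised kNN graph."""
    if t <= 0:
        raise ValueError(f"kernel width t must be > 0, got {t}")
    V = _as_cells_matrix(X)
    n = V.shape[1]
    if k is None:
        k = default_knn(n)
    neigh = knn_sets(V, k)
    mask = np.zeros((n, n), dtype=bool)
    for i, js in enumerate(neigh):
        mask[i, js] = True
    mask |= mask.T
    np.fill_diagonal(mask, False)

    sq = np.sum(V * V, axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (V.T @ V)
    np.maximum(d2, 0.0, out=d2)
    S = np.where(mask, np.exp(-d2 / (2.0 * t * t)), 0.0)
    S = 0.5 * (S + S.T)  # kill float asymmetry from the distance matrix
    D, L = laplacian(S)
    return AffinityGraph(S=S, D=D, L=L, k=k, t=float(t))
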