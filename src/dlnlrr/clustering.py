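"""Direct clustering from the low-rank representation H and the
|H^T H| block diagnostic used to choose the subspace count r.

Each column of H is the projection of one cell onto the r learned
subspaces, so the cell is assigned to the subspace with the largest
projection — no spectral clustering step is involved.  When r matches
the true cluster count, |H^T H| (cells ordered by cluster) shows a
block-diagonal pattern whose block count stops growing as r increases
past the truth; that plateau identifies r.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .solver import SolverConfig, SolverState, fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusteringResult:
    """Hard labels (1-based) plus H and its |H^T H| diagnostic."""

    labels: np.ndarray
    H: np.ndarray
    gram_abs: np.ndarray
    r: int


def assign_labels(H: np.ndarray) -> np.ndarray:
    """Per-column argmax of H, 1-based; ties break to the smallest row
    index and an all-zero column falls to cluster 1 with a warning."""
    H = np.asarray(H, dtype=float)
    if H.size == 0:
        raise ValueError("empty H")
    if not np.all(np.isfinite(H)):
        raise ValueError("H contains non-finite entries")
    n_zero = int(np.sum(~H.any(axis=0)))
    if n_zero:
        logger.warning("%d all-zero column(s) in H assigned to cluster 1", n_zero)
    return np.argmax(H, axis=0) + 1


def gram_diagnostic(H: np.ndarray) -> np.ndarray:
    """|H^T H| — the absolute Gram matrix of the cells' low-rank
    coordinates, whose diagonal-block count mirrors the cluster count."""
    H = np.asarray(H, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("H contains non-finite entries")
    return np.abs(H.T @ H)


def cluster(state: SolverState) -> ClusteringResult:
    """Package argmax labels and the Gram diagnostic from a fitted state."""
    return ClusteringResult(
        labels=assign_labels(state.H),
        H=state.H,
        gram_abs=gram_diagnostic(state.H),
        r=state.H.shape[0],
    )


def plot_gram(gram_abs: np.ndarray, path=None, ax=None, order=None):
    """Heatmap of |H^T H| (optionally with cells reordered, e.g. by label)
    for visual inspection of the block-diagonal structure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    G = np.asarray(gram_abs, dtype=float)
    if order is not None:
        G = G[np.ix_(order, order)]
    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 4))
    else:
        fig = ax.figure
    im = ax.imshow(G, cmap="viridis", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("cell")
    ax.set_ylabel("cell")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    return fig


def estimate_block_count(
    gram_abs: np.ndarray,
    threshold_quantile: float = 0.9,
    normalize: bool = True,
) -> int:
    """Count diagonal blocks of |H^T H| by thresholding at a quantile of
    its off-diagonal values and counting connected components.

    With ``normalize`` (default) the Gram matrix is first rescaled to
    cosine similarities ``g_ij / sqrt(g_ii g_jj)`` so that per-cell
    magnitude differences do not mask the block pattern; cells with a
    zero diagonal (no representation at all) are left out.  Components
    of a single cell are thresholding artifacts, not visual blocks, and
    are not counted.
    """
    G = np.asarray(gram_abs, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("gram_abs must be square")
    if not 0 <= threshold_quantile < 1:
        raise ValueError("threshold_quantile must lie in [0, 1)")
    n = G.shape[0]
    if n == 1:
        return 1
    if normalize:
        diag = np.sqrt(np.diag(G))
        keep = diag > 1e-12
        G = G[np.ix_(keep, keep)] / np.outer(diag[keep], diag[keep])
        n = G.shape[0]
        if n == 0:
            logger.warning("Gram matrix has an all-zero diagonal; returning 1 block")
            return 1
    off = G[~np.eye(n, dtype=bool)]
    if off.size == 0 or np.allclose(off, off[0]):
        logger.warning("constant off-diagonal Gram matrix; returning 1 block")
        return 1
    thr = np.quantile(off, threshold_quantile)
    adj = (G > thr) & ~np.eye(n, dtype=bool)
    if not adj.any():  # quantile landed on the maximum (heavy ties)
        adj = (G >= thr) & (G > 0) & ~np.eye(n, dtype=bool)
    n_comp, comp = connected_components(adj, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    blocks = int(np.sum(sizes >= 2))
    return max(blocks, 1)


def select_r(
    X,
    L: np.ndarray,
    config: SolverConfig,
    r_grid: list[int],
    threshold_quantile: float = 0.9,
) -> tuple[int, dict[int, dict]]:
    """Fit once per r in ``r_grid`` and pick the plateau point of the
    block-count curve.

    The chosen r* is the smallest r with ``block_count(r) == r`` whose
    block count does not increase at the next grid value (for the
    largest grid value the plateau check is vacuous).  If no r
    qualifies, the r whose block count is closest to r is returned and
    flagged ``no_plateau`` in the diagnostics.
    """
    if not r_grid:
        raise ValueError("r_grid must be non-empty")
    r_grid = sorted(set(int(r) for r in r_grid))
    diagnostics: dict[int, dict] = {}
    for r in r_grid:
        cfg = dataclasses.replace(config, r=r)
        state = fit(X, L, cfg)
        gram = gram_diagnostic(state.H)
        diagnostics[r] = {
            "block_count": estimate_block_count(gram, threshold_quantile),
            "gram_abs": gram,
            "converged": state.converged,
        }
    for i, r in enumerate(r_grid):
        if diagnostics[r]["block_count"] != r:
            continue
        if i + 1 < len(r_grid):
            nxt = r_grid[i + 1]
            if diagnostics[nxt]["block_count"] > r:
                continue
        return r, diagnostics
    # no plateau: fall back to the r whose block count is nearest to r
    best = min(r_grid, key=lambda r: (abs(diagnostics[r]["block_count"] - r), r))
    diagnostics[best]["no_plateau"] = True
    logger.warning("no plateau in block counts; falling back to r=%d", best)
    return best, diagnostics
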