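"""Marker-gene ranking by bootstrap Laplacian scoring, and 2-D
visualization of the low-rank representation.

The Laplacian score of a gene measures how well its expression respects
the local cell-cell geometry: genes varying smoothly over the graph
(low score) separate the graph's communities and are marker-like, while
genes fluctuating independently of it score near 1.  Here the cell
graph is rebuilt from the learned low-rank coordinates H, so the
ranking reflects the structure the model discovered, and expression
features come from the preprocessed matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .graph import gaussian_affinity, laplacian
from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerRanking:
    """Genes ordered by increasing aggregate score (best marker first)."""

    gene_ids: tuple[str, ...]
    scores: np.ndarray
    per_cluster_expression: pd.DataFrame | None = None


def laplacian_score(X, S: np.ndarray) -> np.ndarray:
    """He-Cai-Niyogi Laplacian score per gene against cell affinity S.

    For gene vector f over cells, with D, L from S:
    center ``f~ = f - (f' D 1 / 1' D 1) 1`` and score
    ``(f~' L f~) / (f~' D f~)``.  Lower is more locality-preserving.
    Constant genes carry no locality information and score 1.
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    S = np.asarray(S, dtype=float)
    if S.shape[0] != S.shape[1] or S.shape[0] != V.shape[1]:
        raise ValueError("S must be n_cells x n_cells")
    D, L = laplacian(S)
    d = np.diag(D)
    d_tot = d.sum()
    if d_tot == 0:
        raise ValueError("affinity graph has no edges")
    F = V - ((V @ d) / d_tot)[:, None]  # degree-weighted centering per gene
    num = np.einsum("gi,ij,gj->g", F, L, F)
    den = (F * F) @ d
    scores = np.ones(V.shape[0])
    ok = den > 1e-12
    scores[ok] = num[ok] / den[ok]
    n_const = int((~ok).sum())
    if n_const:
        logger.warning("%d constant gene(s) assigned Laplacian score 1", n_const)
    return scores


def graph_from_H(H: np.ndarray, k: int | None = None, t: float = 1.0) -> np.ndarray:
    """Cell affinity built from the columns of the low-rank matrix H."""
    return gaussian_affinity(np.asarray(H, dtype=float), k=k, t=t).S


def bootstrap_markers(
    X,
    S: np.ndarray,
    n_boot: int = 100,
    top_k: int = 10,
    seed: int = 0,
) -> MarkerRanking:
    """Rank genes by mean Laplacian-score rank over cell bootstraps.

    Cells are resampled with replacement ``n_boot`` times; each
    replicate induces a submatrix of X and S on which genes are scored
    and ranked, and the aggregate per-gene score is the mean rank
    (robust to score-scale drift across replicates).  With
    ``n_boot=0`` the plain full-sample ranking is returned.
    """
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    gene_ids = (
        X.gene_ids
        if isinstance(X, ExpressionMatrix)
        else tuple(f"gene_{i}" for i in range(V.shape[0]))
    )
    m, n = V.shape
    if top_k > m:
        logger.warning("top_k=%d clamped to gene count %d", top_k, m)
        top_k = m
    rng = np.random.default_rng(seed)
    if n_boot == 0:
        agg = laplacian_score(V, S)
    else:
        ranks = np.zeros((n_boot, m))
        for b in range(n_boot):
            idx = np.sort(rng.integers(0, n, size=n))
            s = laplacian_score(V[:, idx], S[np.ix_(idx, idx)])
            ranks[b] = np.argsort(np.argsort(s))
        agg = ranks.mean(axis=0)
    order = np.argsort(agg, kind="stable")[:top_k]
    return MarkerRanking(
        gene_ids=tuple(gene_ids[i] for i in order),
        scores=agg[order],
    )


def embed_tsne(H: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """t-SNE embedding of the cells' low-rank coordinates (columns of H)."""
    H = np.asarray(H, dtype=float)
    n = H.shape[1]
    if n < 5:
        raise ValueError(f"t-SNE needs at least 5 cells, got {n}")
    perp = min(perplexity, (n - 1) / 3)
    ts = TSNE(
        n_components=2,
        perplexity=perp,
        random_state=seed,
        init="pca",
        n_jobs=1,
    )
    return ts.fit_transform(H.T)


def marker_table(X, labels, gene_ids) -> pd.DataFrame:
    """Per (gene, cluster) mean expression and percent of expressing cells."""
    V = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)
    all_ids = (
        list(X.gene_ids)
        if isinstance(X, ExpressionMatrix)
        else [f"gene_{i}" for i in range(V.shape[0])]
    )
    labels = np.asarray(labels)
    rows = []
    for g in gene_ids:
        if g not in all_ids:
            raise KeyError(f"unknown gene id {g!r}")
        gi = all_ids.index(g)
        for c in np.unique(labels):
            in_c = labels == c
            vals = V[gi, in_c]
            rows.append(
                {
                    "gene": g,
                    "cluster": int(c),
                    "mean_expression": float(vals.mean()),
                    "pct_expressing": float(100.0 * np.mean(vals > 0)),
                }
            )
    return pd.DataFrame(rows)


def dotplot_markers(X, labels, ranking: MarkerRanking, top_k: int = 10, ax=None):
    """Dot plot: color = mean expression, size = percent expressing.

    Returns (figure, table); the table is the tidy per-(gene, cluster)
    summary behind the plot.
    """
    import matplotlib.pyplot as plt

    genes = list(ranking.gene_ids[:top_k])
    table = marker_table(X, labels, genes)
    if ax is None:
        fig, ax = plt.subplots(figsize=(1 + 0.6 * len(genes), 3))
    else:
        fig = ax.figure
    clusters = sorted(table["cluster"].unique())
    for _, row in table.iterrows():
        ax.scatter(
            genes.index(row["gene"]),
            clusters.index(row["cluster"]),
            s=5 + row["pct_expressing"],
            c=[[row["mean_expression"]]],
            cmap="viridis",
            vmin=0,
            vmax=max(table["mean_expression"].max(), 1e-12),
        )
    ax.set_xticks(range(len(genes)), genes, rotation=90)
    ax.set_yticks(range(len(clusters)), [f"cluster {c}" for c in clusters])
    ax.set_xlabel("gene")
    fig.tight_layout()
    return fig, table
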