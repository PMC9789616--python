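"""Synthetic data generators.

Two fixture families cover the method's two faces:

* :func:`make_subspace_data` draws points from a union of mutually
  orthogonal low-dimensional linear subspaces — the geometric model
  under which low-rank representation provably segments samples;
* :func:`make_count_data` emulates a toy scRNA-seq count matrix:
  per-cluster log-normal mean profiles, Poisson counts, and uniform
  Bernoulli dropout, plus a floor of near-silent genes so the gene
  filter has something to remove.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import ExpressionMatrix


@dataclass(frozen=True)
class SubspaceSpec:
    """Geometry of a union-of-subspaces draw.

    r subspaces of intrinsic dimension d in ambient dimension m, n_per
    points each, i.i.d. Gaussian noise of sd ``noise_sd`` added to every
    coordinate.  ``overlap`` in [0, 1) rotates each basis towards a
    shared direction to create harder, non-orthogonal instances.
    """

    r: int = 3
    d: int = 2
    m: int = 30
    n_per: int = 40
    noise_sd: float = 0.0
    overlap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d >= self.m:
            raise ValueError("need d < m")
        if self.r * self.d > self.m:
            raise ValueError("r*d must not exceed m for orthogonal subspaces")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must lie in [0, 1)")


def make_subspace_data(spec: SubspaceSpec) -> tuple[np.ndarray, np.ndarray]:
    """Sample a union of r orthogonal d-dim subspaces in R^m.

    Returns a genes-by-cells shaped array ``(m, r * n_per)`` and the
    1-based ground-truth labels.  Coefficients are non-negative with
    unit norm, so points lie on the unit sphere inside the non-negative
    cone of their subspace before noise — the regime a non-negative
    representation H >= 0 can encode with one dictionary atom per
    subspace (signed coefficients would need antipodal atom pairs).
    """
    rng = np.random.default_rng(spec.seed)
    basis, _ = np.linalg.qr(rng.standard_normal((spec.m, spec.r * spec.d)))
    shared = basis[:, :1]
    cols = []
    labels = []
    for k in range(spec.r):
        B = basis[:, k * spec.d : (k + 1) * spec.d]
        if spec.overlap > 0:
            B = (1 - spec.overlap) * B + spec.overlap * np.tile(shared, (1, spec.d))
            B, _ = np.linalg.qr(B)
        coef = np.abs(rng.standard_normal((spec.d, spec.n_per)))
        coef /= np.linalg.norm(coef, axis=0, keepdims=True)
        cols.append(B @ coef)
        labels.extend([k + 1] * spec.n_per)
    X = np.concatenate(cols, axis=1)
    if spec.noise_sd > 0:
        X = X + spec.noise_sd * rng.standard_normal(X.shape)
    return X, np.asarray(labels, dtype=int)


def make_count_data(
    r: int = 3,
    genes: int = 200,
    n_per: int = 40,
    dropout_rate: float = 0.0,
    seed: int = 0,
    mean_log: float = 1.0,
    sd_log: float = 1.0,
    frac_rare: float = 0.1,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Toy scRNA-seq raw counts with cluster structure and dropout.

    Each cluster k gets a log-normal mean profile ``exp(N(mean_log,
    sd_log^2))`` per gene; counts are Poisson around the profile and
    then independently zeroed with probability ``dropout_rate``.  A
    fraction ``frac_rare`` of genes is near-silent (expressed in at most
    two randomly chosen cells) so the downstream gene filter is
    exercised.  Returns an ExpressionMatrix of raw counts plus 1-based
    true labels.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = r * n_per
    n_rare = int(round(frac_rare * genes))
    n_expr = genes - n_rare

    profiles = rng.lognormal(mean=mean_log, sigma=sd_log, size=(n_expr, r))
    lam = np.repeat(profiles, n_per, axis=1)
    counts = rng.poisson(lam).astype(float)
    if dropout_rate > 0:
        counts[rng.random(counts.shape) < dropout_rate] = 0.0

    rare = np.zeros((n_rare, n))
    for i in range(n_rare):
        k = rng.integers(0, 3)  # expressed in 0, 1 or 2 cells
        if k:
            idx = rng.choice(n, size=k, replace=False)
            rare[i, idx] = rng.integers(1, 5, size=k)

    values = np.vstack([counts, rare])
    gene_ids = tuple(f"gene_{i}" for i in range(genes))
    cell_ids = tuple(f"cell_{j}" for j in range(n))
    labels = np.repeat(np.arange(1, r + 1), n_per)
    return ExpressionMatrix(values, gene_ids, cell_ids, ("simulated",)), labels
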