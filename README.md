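# dlnlrr

Non-negative low-rank representation with a **learnable dictionary** for
clustering single-cell RNA-seq data.

Subspace-clustering methods for scRNA-seq usually learn a cell-cell
similarity matrix first and then hand it to a spectral clustering step, and
they typically use the noisy expression matrix itself as the dictionary
against which cells are represented. This package implements an alternative:
the dictionary is modelled as a linear combination of the data, `A = XW`,
and is re-learned during optimization, while cluster labels are read
directly off the representation matrix — no spectral clustering step.

## Model

Given a preprocessed genes × cells matrix `X ∈ R^{m×n}`, the method solves

```
min_{W,H}  ½‖X − XWH‖²_F + λ‖H‖_* + β tr(H L Hᵀ)
s.t.       WᵀW = I_r,   H ≥ 0
```

where `W ∈ R^{n×r}` holds the dictionary coefficients (`XW` is the
dictionary, one atom per subspace), `H ∈ R^{r×n}` is the non-negative
low-rank representation, `‖·‖_*` is the nuclear norm, and `L` is the
Laplacian of a kNN Gaussian affinity graph over cells, which keeps cells
that are close in expression space close in the representation. The
problem is solved by a linearized ADMM scheme with adaptive penalty
(auxiliary splits `J = H` and `Z = WH`; singular-value thresholding for
`J`, a linear solve for `Z`, an orthogonal-Procrustes step for `W`, a
Sylvester equation for `H`, then multiplier and penalty updates).

Because column `j` of `H` is the projection of cell `j` onto the `r`
learned subspaces, the cell's cluster is simply `argmax_i H[i, j]`. The
number of subspaces `r` is chosen from data via the block count of the
`|HᵀH|` heatmap, which stops growing once `r` reaches the true cluster
number (`select_r`).

## Worked example

`examples/02_count_pipeline.py` simulates raw counts for three cell types
with 30 % dropout and runs the full pipeline — gene filtering (drop genes
detected in ≤ 2 cells), median library-size normalization, `log10(x+1)`,
graph construction, model fitting, argmax labelling:

```
$ python examples/02_count_pipeline.py
raw matrix: 200 genes x 120 cells, 47% zeros
after gene filter: 180 genes (steps: filter_genes -> median_normalize -> log_transform)
ARI = 1.000, NMI = 1.000
```

The adjusted Rand index and normalized mutual information compare the
inferred labels with the simulated ground truth; 1.0 means the three cell
types were recovered exactly despite the dropout noise. The other examples
cover subspace recovery (`01`), data-driven selection of `r` (`03`),
marker-gene ranking by bootstrap Laplacian scoring plus t-SNE on `H`
(`04`), and a λ/β grid sweep (`05`).

A thin CLI wraps the same pipeline:

```
dlnlrr simulate --mode counts --r 3 --out sim
dlnlrr fit --input sim.csv --r 3 --out labels.tsv
dlnlrr eval --pred labels.tsv --truth sim.truth.tsv
dlnlrr select-r --input sim.csv --r-min 2 --r-max 8
```

Per-dataset (λ, β) optima for eight published scRNA-seq benchmarks
(Treutlein, Ting, Deng, Pollen, Goolam, Engel, Kolod, Darmanis) ship as
presets: `preset_config("ting", r=5)`.

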