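"""Reading expression matrices and the standard preprocessing pipeline.

The canonical in-memory orientation is genes x cells (one column per cell),
so a matrix ``X`` with ``m`` genes and ``n`` cells has shape ``(m, n)``.
Preprocessing follows the usual three steps for count data: remove genes
detected in too few cells, rescale every cell to the median library size,
and apply a ``log10(x + 1)`` transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite


class ValidationError(ValueError):
    """Raised when a matrix violates a structural contract."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x cells non-negative expression matrix with identifiers.

    Parameters
    ----------
    values
        Dense float array of shape ``(m_genes, n_cells)``; all entries >= 0.
    gene_ids, cell_ids
        Unique identifiers for rows and columns respectively.
    transform_log
        Ordered names of the preprocessing steps already applied.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    cell_ids: tuple[str, ...]
    transform_log: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        object.__setattr__(self, "transform_log", tuple(self.transform_log))
        if values.ndim != 2:
            raise ValidationError(f"expected a 2-D matrix, got ndim={values.ndim}")
        m, n = values.shape
        if m != len(self.gene_ids):
            raise ValidationError(
                f"{m} rows but {len(self.gene_ids)} gene identifiers"
            )
        if n != len(self.cell_ids):
            raise ValidationError(
                f"{n} columns but {len(self.cell_ids)} cell identifiers"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell identifiers")
        if not np.all(np.isfinite(values)):
            raise ValidationError("matrix contains non-finite entries")
        if values.size and values.min() < 0:
            raise ValidationError("matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.cell_ids))


def read_matrix(
    path: str | Path,
    format: str = "csv",
    orientation: str = "genes_by_cells",
) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV (with id header and index) or
    MatrixMarket (with ``genes.txt`` / ``barcodes.txt`` sidecars).

    Whatever the on-disk orientation, the returned matrix is genes x cells.
    """
    path = Path(path)
    if format not in {"csv", "tsv", "mtx"}:
        raise ValueError(f"unknown format {format!r}")
    if orientation not in {"genes_by_cells", "cells_by_genes"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "mtx":
        # mmread returns coo for sparse files, ndarray for array-format files
        raw = mmread(str(path))
        values = np.asarray(raw.todense() if hasattr(raw, "todense") else raw, dtype=float)
        row_file = path.with_name("genes.txt" if orientation == "genes_by_cells" else "barcodes.txt")
        col_file = path.with_name("barcodes.txt" if orientation == "genes_by_cells" else "genes.txt")
        for f in (row_file, col_file):
            if not f.exists():
                raise FileNotFoundError(f"MTX sidecar identifier file missing: {f}")
        row_ids = [ln.strip() for ln in row_file.read_text().splitlines() if ln.strip()]
        col_ids = [ln.strip() for ln in col_file.read_text().splitlines() if ln.strip()]
        if orientation == "genes_by_cells":
            gene_ids, cell_ids = row_ids, col_ids
        else:
            values = values.T
            gene_ids, cell_ids = col_ids, row_ids
    else:
        sep = "," if format == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValidationError(f"failed to parse {path}: {exc}") from exc
        non_numeric = df.columns[
            [not np.issubdtype(dt, np.number) for dt in df.dtypes]
        ]
        if len(non_numeric):
            raise ValidationError(
                f"non-numeric columns in {path}: {list(non_numeric)[:5]}"
            )
        if orientation == "cells_by_genes":
            df = df.T
        values = df.to_numpy(dtype=float)
        gene_ids = [str(i) for i in df.index]
        cell_ids = [str(c) for c in df.columns]

    return ExpressionMatrix(values, tuple(gene_ids), tuple(cell_ids), ("read",))


def write_matrix(X: ExpressionMatrix, path: str | Path, format: str = "csv") -> None:
    """Write genes x cells to CSV/TSV (ids in header/index) or MTX + sidecars."""
    path = Path(path)
    if format == "mtx":
        mmwrite(str(path), np.asarray(X.values))
        path.with_name("genes.txt").write_text("\n".join(X.gene_ids) + "\n")
        path.with_name("barcodes.txt").write_text("\n".join(X.cell_ids) + "\n")
    else:
        X.to_dataframe().to_csv(path, sep="," if format == "csv" else "\t")


def filter_genes(X: ExpressionMatrix, min_cells_exclusive: int = 2) -> ExpressionMatrix:
    """Keep genes expressed (count > 0) in strictly more than
    ``min_cells_exclusive`` cells; the default drops genes detected in two
    or fewer cells."""
    if min_cells_exclusive < 0:
        raise ValueError("min_cells_exclusive must be >= 0")
    n_expressing = (X.values > 0).sum(axis=1)
    keep = n_expressing > min_cells_exclusive
    if not keep.any():
        raise ValidationError("empty matrix after filtering: no gene passes the threshold")
    return ExpressionMatrix(
        X.values[keep],
        tuple(g for g, k in zip(X.gene_ids, keep) if k),
        X.cell_ids,
        X.transform_log + ("filter_genes",),
    )


def median_normalize(X: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell so its library size equals the median library size.

    The size factor of cell ``j`` is ``library_size(j) / median(library
    sizes)`` and counts are divided by it.
    """
    lib = X.values.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValidationError(
            f"cell(s) with zero library size: {[X.cell_ids[j] for j in zero[:5]]}"
        )
    med = float(np.median(lib))
    return ExpressionMatrix(
        X.values * (med / lib),
        X.gene_ids,
        X.cell_ids,
        X.transform_log + ("median_normalize",),
    )


def log_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise ``log10(x + 1)``; zeros stay zero."""
    if "log_transform" in X.transform_log:
        raise ValidationError("log transform already applied")
    return ExpressionMatrix(
        np.log10(X.values + 1.0),
        X.gene_ids,
        X.cell_ids,
        X.transform_log + ("log_transform",),
    )


def preprocess(
    X: ExpressionMatrix,
    min_cells_exclusive: int = 2,
    normalize: bool = True,
    log: bool = True,
) -> ExpressionMatrix:
    """Full pipeline: gene filter, then median normalization, then log."""
    X = filter_genes(X, min_cells_exclusive)
    if normalize:
        X = median_normalize(X)
    if log:
        X = log_transform(X)
    return X
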