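"""Expression-matrix containers and readers.

The canonical in-memory orientation is genes x cells, matching the common
on-disk layout of dense single-cell text matrices and MatrixMarket triplets.
Values are expected to be non-negative, finite, log-scale expression; the
downstream pair score and enrichment test are rank-based, so any monotone
per-cell normalization yields identical results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClusterAssignment",
    "read_dense_matrix",
    "read_mtx",
    "normalize_log",
]


@dataclass
class ExpressionMatrix:
    """Genes x cells expression with optional per-cell metadata.

    Parameters
    ----------
    genes : array of unique gene symbols (rows).
    cells : array of unique cell barcodes (columns).
    values : (n_genes, n_cells) dense array or scipy sparse matrix of
        non-negative finite values.
    cell_meta : optional DataFrame indexed by cell barcode (columns such as
        ``patient``, ``cluster``, ``malignant``).
    """

    genes: np.ndarray
    cells: np.ndarray
    values: np.ndarray | scipy.sparse.spmatrix
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        if scipy.sparse.issparse(self.values):
            self.values = scipy.sparse.csc_matrix(self.values)
            data = self.values.data
        else:
            self.values = np.asarray(self.values, dtype=float)
            data = self.values
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            self._aggregate_duplicate_genes()
            data = self.values.data if scipy.sparse.issparse(self.values) else self.values
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell barcodes")
        if data.size and (not np.all(np.isfinite(data)) or np.min(data, initial=0) < 0):
            raise ValueError("expression values must be non-negative and finite")
        if self.cell_meta is not None:
            missing = set(self.cells) - set(self.cell_meta.index)
            if missing:
                raise ValueError(f"{len(missing)} cell(s) absent from cell_meta")
            self.cell_meta = self.cell_meta.loc[list(self.cells)]

    def _aggregate_duplicate_genes(self) -> None:
        # duplicated symbols are collapsed by per-cell max, keeping first position
        warnings.warn("duplicate gene symbols aggregated by max")
        dense = self.to_dense()
        order: dict[str, int] = {}
        for g in self.genes:
            order.setdefault(g, len(order))
        agg = np.zeros((len(order), dense.shape[1]))
        np.maximum.at(agg, [order[g] for g in self.genes], dense)
        self.genes = np.array(list(order), dtype=object)
        self.values = agg

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_dense(self) -> np.ndarray:
        if scipy.sparse.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def to_frame(self) -> pd.DataFrame:
        """Cells x genes DataFrame (the estimator-facing orientation)."""
        return pd.DataFrame(self.to_dense().T, index=self.cells, columns=self.genes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def subset_cells(self, barcodes: np.ndarray | list) -> "ExpressionMatrix":
        idx = {c: i for i, c in enumerate(self.cells)}
        cols = [idx[b] for b in barcodes]
        values = self.values[:, cols]
        meta = self.cell_meta.iloc[cols] if self.cell_meta is not None else None
        return ExpressionMatrix(self.genes.copy(), np.asarray(barcodes, dtype=object),
                                values, meta)


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels with a pair of clusters under comparison."""

    labels: pd.Series  # index: cell_id, values: cluster label
    cluster_a: str | None = None
    cluster_b: str | None = None

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate cell ids in cluster assignment")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.labels.index) - set(matrix.cells)
        if missing:
            raise ValueError(f"{len(missing)} assigned cell(s) absent from the matrix")

    def member_cells(self, cluster: str) -> list:
        cells = list(self.labels.index[self.labels == cluster])
        if not cells:
            raise ValueError(f"cluster {cluster!r} has no cells")
        return cells

    def split(self) -> tuple[list, list]:
        if self.cluster_a is None or self.cluster_b is None:
            raise ValueError("cluster_a and cluster_b must be set")
        if self.cluster_a == self.cluster_b:
            raise ValueError("the two clusters under comparison must differ")
        return self.member_cells(self.cluster_a), self.member_cells(self.cluster_b)


def read_dense_matrix(
    path: str | Path,
    sep: str | None = None,
    orient: str = "genes_by_cells",
    uppercase: bool = True,
) -> ExpressionMatrix:
    """Read a dense TSV/CSV expression matrix (genes in rows by default).

    The first column holds gene symbols and the header row holds cell ids.
    ``orient="cells_by_genes"`` transposes on read.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if orient == "cells_by_genes":
        df = df.T
    elif orient != "genes_by_cells":
        raise ValueError(f"unknown orient: {orient!r}")
    values = df.to_numpy(dtype=float)  # raises on non-numeric entries
    genes = df.index.astype(str).to_numpy(dtype=object)
    if uppercase:
        genes = np.array([g.upper() for g in genes], dtype=object)
    cells = df.columns.astype(str).to_numpy(dtype=object)
    return ExpressionMatrix(genes, cells, values)


def read_mtx(
    directory: str | Path,
    matrix_file: str = "matrix.mtx",
    features_file: str = "features.tsv",
    barcodes_file: str = "barcodes.tsv",
    uppercase: bool = True,
) -> ExpressionMatrix:
    """Read a MatrixMarket triplet directory (10x-style layout).

    ``features.tsv`` (or ``genes.tsv``) rows map to matrix rows; the gene
    symbol is taken from the last text column.  The matrix stays sparse
    internally.
    """
    directory = Path(directory)
    mtx_path = directory / matrix_file
    feat_path = directory / features_file
    if not feat_path.exists() and (directory / "genes.tsv").exists():
        feat_path = directory / "genes.tsv"
    bc_path = directory / barcodes_file
    values = scipy.sparse.csc_matrix(scipy.io.mmread(mtx_path))
    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    genes = feats.iloc[:, -1] if feats.shape[1] == 1 else feats.iloc[:, 1]
    genes = genes.to_numpy(dtype=object)
    if uppercase:
        genes = np.array([g.upper() for g in genes], dtype=object)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str).iloc[:, 0].to_numpy(dtype=object)
    if values.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"mtx header {values.shape} does not match {len(genes)} features "
            f"x {len(barcodes)} barcodes"
        )
    if values.nnz == 0:
        warnings.warn("matrix contains no non-zero entries")
    return ExpressionMatrix(genes, barcodes, values)


def normalize_log(
    counts: ExpressionMatrix,
    scale: float = 10_000.0,
    force: bool = False,
) -> ExpressionMatrix:
    """Library-size normalize and log-transform raw counts.

    Each cell's counts are scaled to ``scale`` total and transformed as
    ``log(1 + scale * count / total)``.  Cells with zero total counts are
    dropped with a warning.  Non-integer input triggers an
    already-normalized warning (error unless ``force``).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    dense = counts.to_dense()
    if not np.allclose(dense, np.round(dense)):
        if not force:
            raise ValueError(
                "input does not look like raw counts (non-integer values); "
                "pass force=True to normalize anyway"
            )
        warnings.warn("non-integer input treated as counts (force=True)")
    totals = dense.sum(axis=0)
    keep = totals > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} all-zero cell(s)")
    dense = dense[:, keep]
    totals = totals[keep]
    out = np.log1p(scale * dense / totals)
    meta = counts.cell_meta.loc[counts.cells[keep]] if counts.cell_meta is not None else None
    return ExpressionMatrix(counts.genes.copy(), counts.cells[keep], out, meta)
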