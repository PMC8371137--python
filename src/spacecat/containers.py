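"""Core in-memory containers shared across the toolkit.

Expression data are held genes x cells, mirroring the orientation of MTX
digital gene expression exports (rows = genes, columns = cell barcodes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["CountMatrix", "ExpressionMatrix"]


def _as_string_array(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.ndim != 1:
        raise ValueError(f"{what} must be one-dimensional")
    return np.array([str(v) for v in arr], dtype=object)


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifiers.

    Parameters
    ----------
    matrix : scipy sparse or dense array, shape (n_genes, n_cells)
        Non-negative integer counts.
    genes : sequence of str
        Gene identifiers (case-sensitive, duplicates rejected).
    cells : sequence of str
        Cell barcodes (duplicates rejected).
    """

    matrix: sp.csr_matrix
    genes: np.ndarray
    cells: np.ndarray

    def __post_init__(self):
        if not sp.issparse(self.matrix):
            self.matrix = sp.csr_matrix(np.asarray(self.matrix))
        else:
            self.matrix = self.matrix.tocsr()
        self.genes = _as_string_array(self.genes, "genes")
        self.cells = _as_string_array(self.cells, "cells")
        n_genes, n_cells = self.matrix.shape
        if len(self.genes) != n_genes:
            raise ValueError(
                f"gene identifiers ({len(self.genes)}) do not match matrix rows ({n_genes})"
            )
        if len(self.cells) != n_cells:
            raise ValueError(
                f"cell barcodes ({len(self.cells)}) do not match matrix columns ({n_cells})"
            )
        for name, ids in (("gene", self.genes), ("cell", self.cells)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} identifiers are not allowed")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")
        data = self.matrix.data
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("counts must be integers")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Per-cell total UMI counts (column sums)."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of detected (nonzero) genes per cell."""
        return np.asarray((self.matrix > 0).sum(axis=0)).ravel()

    def gene_index(self, names) -> np.ndarray:
        """Row indices for gene names; raises KeyError on missing genes."""
        lookup = {g: i for i, g in enumerate(self.genes)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene not found: {exc.args[0]}") from None

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.matrix[:, idx], self.genes, self.cells[idx])

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


@dataclass
class ExpressionMatrix:
    """Genes x cells log-normalized expression, e = ln(1 + s * x / T).

    Zeros in the count matrix remain exactly zero, so sparsity is preserved.
    """

    matrix: sp.csr_matrix
    genes: np.ndarray
    cells: np.ndarray
    scale: float = 10_000.0
    cell_totals: np.ndarray = field(default=None)

    def __post_init__(self):
        if not sp.issparse(self.matrix):
            self.matrix = sp.csr_matrix(np.asarray(self.matrix, dtype=float))
        else:
            self.matrix = self.matrix.tocsr().astype(float)
        self.genes = _as_string_array(self.genes, "genes")
        self.cells = _as_string_array(self.cells, "cells")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers are not allowed")
        if self.matrix.shape != (len(self.genes), len(self.cells)):
            raise ValueError("identifier lengths do not match matrix shape")
        if self.cell_totals is not None:
            self.cell_totals = np.asarray(self.cell_totals, dtype=float)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def gene_index(self, names) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene not found: {exc.args[0]}") from None

    def gene_means(self) -> np.ndarray:
        """Mean log-normalized expression per gene across all cells."""
        return np.asarray(self.matrix.mean(axis=1)).ravel()

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())
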