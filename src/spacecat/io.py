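"""Readers and writers for the toolkit's on-disk formats.

Counts move as Matrix Market (MTX, 1-based per the standard) with
``genes.tsv``/``barcodes.tsv`` sidecars, or as a dense CSV whose header row
holds cell barcodes and whose first column holds gene names. Images move as
TIFF (via tifffile) or dense CSV grids. All round-trips are lossless for
integer counts.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import tifffile

from .containers import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_image",
    "write_image",
]


def write_counts(counts: CountMatrix, path: str | os.PathLike) -> None:
    """Write counts as MTX + sidecars (path is a directory) or dense CSV.

    A path ending in ``.csv`` gets the dense form; anything else is treated
    as a directory receiving ``matrix.mtx``, ``genes.tsv``, ``barcodes.tsv``.
    """
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.DataFrame(counts.to_dense().astype(int), index=counts.genes,
                          columns=counts.cells)
        df.to_csv(path, index_label="gene")
        return
    path.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(path / "matrix.mtx"), counts.matrix.astype(int))
    pd.Series(counts.genes).to_csv(path / "genes.tsv", sep="\t", index=False,
                                   header=False)
    pd.Series(counts.cells).to_csv(path / "barcodes.tsv", sep="\t", index=False,
                                   header=False)


def read_counts(path: str | os.PathLike) -> CountMatrix:
    """Read counts written by :func:`write_counts` (MTX directory or CSV)."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(sp.csr_matrix(df.to_numpy()), list(df.index),
                           list(df.columns))
    mtx_path = path / "matrix.mtx"
    if not mtx_path.exists():
        raise FileNotFoundError(f"no matrix.mtx under {path}")
    matrix = sp.csr_matrix(sio.mmread(str(mtx_path)))
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if matrix.shape != (len(genes), len(cells)):
        raise ValueError(
            f"MTX shape {matrix.shape} does not match sidecars "
            f"({len(genes)} genes, {len(cells)} barcodes)"
        )
    return CountMatrix(matrix, list(genes), list(cells))


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, index_label=meta.index.name or "cell")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write a grid as TIFF (``.tif``/``.tiff``) or CSV.

    Integer images are stored as 16-bit (or 8-bit for binary masks).
    """
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in {".tif", ".tiff"}:
        if image.dtype == bool:
            out = image.astype(np.uint8) * 255
        elif np.issubdtype(image.dtype, np.integer):
            if image.min() < 0 or image.max() > np.iinfo(np.uint16).max:
                raise ValueError("integer image out of 16-bit range")
            out = image.astype(np.uint16)
        else:
            out = image.astype(np.float32)
        tifffile.imwrite(str(path), out)
    else:
        np.savetxt(path, image, delimiter=",", fmt="%.10g")


def read_image(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return np.asarray(tifffile.imread(str(path)))
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
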