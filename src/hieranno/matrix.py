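"""Gene-by-cell matrix containers and readers/writers.

Counts are stored dense (genes in rows, cells in columns); inputs at the
scale this tool targets (thousands of cells, a marker-panel-sized gene
space) fit comfortably in memory. Readers accept 10x-style Matrix Market
triplet directories and dense TSV/CSV tables; gzip is handled
transparently for the triplet members.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class MatrixError(ValueError):
    """Raised for malformed or inconsistent matrix inputs."""


@dataclass
class CountMatrix:
    """Raw non-negative integer counts, genes x cells."""

    values: np.ndarray  # (n_genes, n_cells), integer
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if scipy.sparse.issparse(self.values):  # pragma: no cover - guarded by asarray
            self.values = self.values.toarray()
        if self.values.ndim != 2:
            raise MatrixError("count matrix must be two-dimensional")
        if self.values.shape != (len(self.genes), len(self.barcodes)):
            raise MatrixError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if np.any(self.values < 0):
            raise MatrixError("counts must be non-negative")
        if len(set(self.genes)) != len(self.genes):
            raise MatrixError("gene identifiers must be unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise MatrixError("cell barcodes must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            self.values[:, index],
            list(self.genes),
            [self.barcodes[i] for i in index],
        )


@dataclass
class ExpressionMatrix:
    """Normalized log expression, genes x cells (same identifiers as counts)."""

    values: np.ndarray  # (n_genes, n_cells), float
    genes: list[str]
    barcodes: list[str]
    scale_to: float = 10_000.0
    _gene_index: dict = field(default=None, repr=False, compare=False)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict:
        """Case-insensitive symbol -> row lookup (first occurrence wins)."""
        if self._gene_index is None:
            idx: dict = {}
            for i, g in enumerate(self.genes):
                idx.setdefault(g.upper(), i)
            self._gene_index = idx
        return self._gene_index


def _open_maybe_gz(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_member(directory: str, stems: list[str]) -> str:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = os.path.join(directory, stem + suffix)
            if os.path.exists(p):
                return p
    raise FileNotFoundError(
        f"none of {stems} found in {directory!r} (plain or .gz)"
    )


def read_10x_mtx(directory: str) -> CountMatrix:
    """Read a 10x-style triplet: matrix.mtx + features/genes.tsv + barcodes.tsv."""
    mtx_path = _find_member(directory, ["matrix.mtx"])
    feat_path = _find_member(directory, ["features.tsv", "genes.tsv"])
    bc_path = _find_member(directory, ["barcodes.tsv"])
    mat = scipy.io.mmread(mtx_path)
    values = np.asarray(scipy.sparse.coo_matrix(mat).todense())
    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    # 10x features files carry (id, symbol, type); single-column files are symbols
    genes = list(feats.iloc[:, 1] if feats.shape[1] > 1 else feats.iloc[:, 0])
    barcodes = list(pd.read_csv(bc_path, sep="\t", header=None, dtype=str).iloc[:, 0])
    return CountMatrix(np.rint(values).astype(np.int64), genes, barcodes)


def read_dense_counts(path: str, sep: str | None = None) -> CountMatrix:
    """Read a dense table: genes in rows (first column), header row = barcodes."""
    if sep is None:
        sep = "," if path.endswith((".csv", ".csv.gz")) else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy()
    if not np.allclose(values, np.rint(values)):
        raise MatrixError(f"{path}: counts must be integers")
    return CountMatrix(
        np.rint(values).astype(np.int64),
        [str(g) for g in df.index],
        [str(b) for b in df.columns],
    )


def read_counts(path: str) -> CountMatrix:
    """Dispatch on input kind: a directory is a 10x triplet, a file is dense."""
    if os.path.isdir(path):
        return read_10x_mtx(path)
    return read_dense_counts(path)


def write_10x_mtx(counts: CountMatrix, directory: str) -> None:
    """Write a plain-text 10x-style triplet (uncompressed)."""
    os.makedirs(directory, exist_ok=True)
    coo = scipy.sparse.coo_matrix(counts.values)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"), coo, field="integer")
    with open(os.path.join(directory, "features.tsv"), "w") as fh:
        for g in counts.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        for b in counts.barcodes:
            fh.write(b + "\n")
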