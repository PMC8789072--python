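"""Quality control, normalization, variable-gene selection, scaling, PCA.

The pipeline mirrors the standard single-cell recipe: filter low-quality
cells, depth-normalize to 10 000 counts and take ln(1 + x), pick the most
variable genes by variance standardized against a loess fit of the
mean-variance trend, z-scale those genes, and embed cells with PCA. Each
step is exposed separately because the iterative annotation engine re-runs
gene selection, scaling and PCA on every cell subset it descends into.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import CountMatrix, ExpressionMatrix


class PreprocessError(ValueError):
    pass


@dataclass
class QCReport:
    """Cells removed by each criterion (a cell may trip several)."""

    n_input: int
    n_kept: int
    removed_mito: int
    removed_low_umi: int
    removed_low_genes: int
    removed_high_genes: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


def qc_filter(
    counts: CountMatrix,
    mito_prefix: str = "MT-",
    max_mito_frac: float = 0.20,
    min_umi: int = 500,
    min_genes: int = 200,
    max_genes: int = 6000,
) -> tuple[CountMatrix, QCReport]:
    """Drop low-quality cells; thresholds are strict inequalities.

    A cell is excluded iff its mitochondrial fraction is > ``max_mito_frac``,
    its total UMI count is < ``min_umi``, or its number of detected genes is
    < ``min_genes`` or > ``max_genes``. Mitochondrial genes are recognized by
    a case-insensitive symbol prefix (default matches both MT- and mt-).
    """
    totals = counts.values.sum(axis=0)
    n_detected = (counts.values > 0).sum(axis=0)
    prefix = mito_prefix.upper()
    mito_rows = np.array([g.upper().startswith(prefix) for g in counts.genes], dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            totals > 0, counts.values[mito_rows].sum(axis=0) / np.maximum(totals, 1), 0.0
        )
    bad_mito = mito_frac > max_mito_frac
    bad_umi = totals < min_umi
    bad_low = n_detected < min_genes
    bad_high = n_detected > max_genes
    keep = ~(bad_mito | bad_umi | bad_low | bad_high)
    report = QCReport(
        n_input=counts.n_cells,
        n_kept=int(keep.sum()),
        removed_mito=int(bad_mito.sum()),
        removed_low_umi=int(bad_umi.sum()),
        removed_low_genes=int(bad_low.sum()),
        removed_high_genes=int(bad_high.sum()),
    )
    if report.n_kept == 0:
        raise PreprocessError("quality control removed every cell")
    return counts.subset_cells(np.flatnonzero(keep)), report


def normalize(counts: CountMatrix, scale_to: float = 10_000.0) -> ExpressionMatrix:
    """Depth-normalize and log-transform: x = ln(1 + scale_to * c / total)."""
    totals = counts.values.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        raise PreprocessError(
            "cells with zero total counts present; run quality control first"
        )
    values = np.log1p(scale_to * counts.values / totals)
    return ExpressionMatrix(
        values, list(counts.genes), list(counts.barcodes), scale_to=scale_to
    )


def select_hvg(
    expr: ExpressionMatrix | np.ndarray,
    n_top: int = 2000,
    span: float = 0.3,
    genes: list[str] | None = None,
) -> list[str]:
    """Rank genes by variance standardized against the loess trend.

    A loess curve (given span) of log10 variance on log10 mean is fitted
    over genes with nonzero variance; each gene's values are standardized
    by its mean and the trend-predicted standard deviation, clipped at
    sqrt(n_cells), and re-scored by the variance of the clipped values.
    The top ``n_top`` symbols are returned in rank order (row order breaks
    ties). Constant genes are never selected.
    """
    if isinstance(expr, ExpressionMatrix):
        values, genes = expr.values, expr.genes
    else:
        values = np.asarray(expr)
        if genes is None:
            raise ValueError("gene symbols required with a bare array")
    n_cells = values.shape[1]
    if n_cells < 2:
        raise PreprocessError("variable-gene selection needs at least 2 cells")
    means = values.mean(axis=1)
    variances = values.var(axis=1, ddof=1)
    eligible = np.flatnonzero(variances > 0)
    if eligible.size == 0:
        return []
    log_mean = np.log10(np.maximum(means[eligible], 1e-12))
    log_var = np.log10(variances[eligible])
    if eligible.size <= 2 or np.ptp(log_mean) == 0:
        expected_var = variances[eligible]
    else:
        fitted = lowess(log_var, log_mean, frac=span, return_sorted=False)
        expected_var = np.power(10.0, fitted)
    expected_sd = np.sqrt(np.maximum(expected_var, 1e-12))
    clip = np.sqrt(n_cells)
    z = (values[eligible] - means[eligible, None]) / expected_sd[:, None]
    np.clip(z, -clip, clip, out=z)
    std_var = z.var(axis=1, ddof=1)
    # descending score, ascending row index on ties
    order = np.lexsort((eligible, -std_var))
    ranked = [eligible[i] for i in order]
    return [genes[i] for i in ranked[: min(n_top, len(ranked))]]


def scale_genes(
    expr: ExpressionMatrix | np.ndarray,
    genes: list[str],
    clip: float = 10.0,
    all_genes: list[str] | None = None,
) -> np.ndarray:
    """Z-score the selected genes across cells (population sd), clip at ±clip.

    Constant genes scale to all zeros. Returns a (len(genes), n_cells) array
    in the order of ``genes``.
    """
    if isinstance(expr, ExpressionMatrix):
        values, all_genes = expr.values, expr.genes
    else:
        values = np.asarray(expr)
        if all_genes is None:
            raise ValueError("gene symbols required with a bare array")
    row_of = {g: i for i, g in enumerate(all_genes)}
    try:
        rows = [row_of[g] for g in genes]
    except KeyError as exc:
        raise PreprocessError(f"gene {exc.args[0]!r} not in the expression matrix") from None
    sub = values[rows].astype(float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)  # population convention (divide by n)
    scaled = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    np.clip(scaled, -clip, clip, out=scaled)
    return scaled


@dataclass
class EmbeddingMatrix:
    """Cells x components PCA scores with explained-variance diagnostics."""

    scores: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(scaled: np.ndarray, n_comp: int = 50, seed: int = 42) -> EmbeddingMatrix:
    """PCA of the scaled matrix (genes x cells); cells are the observations.

    Components are capped at min(n_comp, n_cells - 1, n_genes). The sign of
    each component is fixed so its largest-magnitude gene loading is
    positive, making the embedding reproducible across SVD backends.
    """
    scaled = np.asarray(scaled, dtype=float)
    n_genes, n_cells = scaled.shape
    if n_cells < 2:
        raise PreprocessError("PCA needs at least 2 cells")
    k = min(n_comp, n_cells - 1, n_genes)
    X = scaled.T  # cells x genes
    solver = "full" if min(X.shape) <= 200 or k >= min(X.shape) - 1 else "randomized"
    model = PCA(n_components=k, svd_solver=solver, random_state=seed)
    scores = model.fit_transform(X)
    flip = np.ones(k)
    for j in range(k):
        loading = model.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            flip[j] = -1.0
    return EmbeddingMatrix(
        scores=scores * flip,
        explained_variance=model.explained_variance_.copy(),
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
    )


def subset_embedding(
    expr: ExpressionMatrix,
    cell_index: np.ndarray,
    n_hvg: int = 2000,
    span: float = 0.3,
    n_pcs: int = 50,
    clip: float = 10.0,
    seed: int = 42,
) -> EmbeddingMatrix:
    """Re-select variable genes, re-scale and re-embed one cell subset.

    This is the unit of work the iterative engine repeats at every descent:
    the mean-variance trend, gene ranking and principal axes are all
    recomputed within the subset so that local structure dominates.
    """
    cell_index = np.asarray(cell_index)
    values = expr.values[:, cell_index]
    hvg = select_hvg(values, n_top=n_hvg, span=span, genes=expr.genes)
    if not hvg:
        raise PreprocessError("no variable genes in subset; cannot embed")
    scaled = scale_genes(values, hvg, clip=clip, all_genes=expr.genes)
    return pca(scaled, n_comp=n_pcs, seed=seed)
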