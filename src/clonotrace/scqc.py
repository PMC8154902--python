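"""Single-cell RNA preprocessing: QC filters, sparsity-aware
median-of-ratios normalization, spline-based HVG selection, knee point.

Cell filtering applies four rules in order: (1) cells in the bottom 5% by
number of expressed genes, (2) cells in the top 1% by total UMI count,
(3) cells with more than 15% mitochondrial counts, and (4) cells deviating
(|z| > 3) from a smoothing-spline fit of expressed genes versus total UMI
on the survivors of rules 1-3. Genes expressed in fewer than 1% of cells
are then dropped.

Normalization is a median-of-ratios scheme adapted to sparse data: the
per-gene reference is the geometric mean over cells actually expressing
the gene, and each cell's size factor is the median ratio over the genes
it expresses. Normalized values are log2(x + 1)-transformed.

Highly variable genes are positive outliers from a mean-variance smoothing
spline on the log2 scale, collected while refitting until no |z| > 3
outliers remain. ``knee_point`` picks a cluster number as the elbow of a
decreasing criterion curve (max distance to the endpoint chord).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import make_smoothing_spline
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Gene x cell UMI counts (sparse), with mitochondrial gene flags."""

    genes: np.ndarray
    cells: np.ndarray
    counts: sp.csr_matrix
    mito: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        self.mito = np.asarray(self.mito, dtype=bool)
        self.counts = sp.csr_matrix(self.counts)
        self.counts.eliminate_zeros()
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError("count matrix shape inconsistent with identifiers")
        if len(self.mito) != len(self.genes):
            raise ValueError("one mitochondrial flag per gene required")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset(
        self,
        gene_mask: np.ndarray | None = None,
        cell_mask: np.ndarray | None = None,
    ) -> "CountMatrix":
        gm = np.ones(self.n_genes, bool) if gene_mask is None else gene_mask
        cm = np.ones(self.n_cells, bool) if cell_mask is None else cell_mask
        return CountMatrix(
            genes=self.genes[gm],
            cells=self.cells[cm],
            counts=self.counts[gm][:, cm],
            mito=self.mito[gm],
        )

    @classmethod
    def from_mtx(
        cls,
        mtx_path: str | Path,
        genes_path: str | Path,
        cells_path: str | Path,
        mito_prefix: str = "MT-",
    ) -> "CountMatrix":
        genes = np.array(Path(genes_path).read_text().split(), dtype=object)
        cells = np.array(Path(cells_path).read_text().split(), dtype=object)
        counts = sp.csr_matrix(mmread(str(mtx_path)))
        mito = np.array([g.startswith(mito_prefix) for g in genes], dtype=bool)
        return cls(genes=genes, cells=cells, counts=counts, mito=mito)

    def to_mtx(
        self, mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
    ) -> None:
        mmwrite(str(mtx_path), sp.coo_matrix(self.counts))
        Path(genes_path).write_text("\n".join(map(str, self.genes)) + "\n")
        Path(cells_path).write_text("\n".join(map(str, self.cells)) + "\n")


@dataclass
class NormalizedMatrix:
    """log2(count / size_factor + 1) values on the filtered axes."""

    genes: np.ndarray
    cells: np.ndarray
    values: sp.csr_matrix
    size_factors: np.ndarray


def _fit_spline(
    x: np.ndarray, y: np.ndarray, lam: float | None = None
):
    """Smoothing spline through (x, y) tolerant of tied x values.

    Duplicated abscissae are collapsed to their mean ordinate with
    proportional weight; the penalty is GCV-chosen when ``lam`` is None.
    Returns None when the support is degenerate (fewer than 4 distinct x).
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    xu, inverse, counts = np.unique(xs, return_inverse=True, return_counts=True)
    if len(xu) < 4:
        return None
    yu = np.zeros(len(xu))
    np.add.at(yu, inverse, ys)
    yu /= counts
    return make_smoothing_spline(xu, yu, w=counts.astype(float), lam=lam)


def filter_cells(
    cm: CountMatrix,
    mito_max: float = 0.15,
    low_gene_quantile: float = 0.05,
    high_umi_quantile: float = 0.01,
    outlier_z: float = 3.0,
    spline_lam: float | None = None,
) -> np.ndarray:
    """Apply the four QC rules in order; return surviving cell identifiers.

    Quantile thresholds are computed on the unfiltered sample and are
    inclusive: cells exactly at a threshold are kept.
    """
    if cm.n_cells < 10:
        raise ValueError("need at least 10 cells for the spline fit")
    X = cm.counts
    genes_per_cell = np.asarray((X > 0).sum(axis=0)).ravel()
    total_umi = np.asarray(X.sum(axis=0)).ravel().astype(float)
    keep = np.ones(cm.n_cells, dtype=bool)
    if low_gene_quantile > 0:
        keep &= genes_per_cell >= np.quantile(genes_per_cell, low_gene_quantile)
    if high_umi_quantile > 0:
        keep &= total_umi <= np.quantile(total_umi, 1.0 - high_umi_quantile)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(
            total_umi > 0,
            np.asarray(X[cm.mito].sum(axis=0)).ravel() / np.maximum(total_umi, 1e-300),
            0.0,
        )
    keep &= mito_frac <= mito_max

    if np.isfinite(outlier_z):
        idx = np.nonzero(keep)[0]
        x = np.log2(total_umi[idx] + 1.0)
        y = np.log2(genes_per_cell[idx] + 1.0)
        spline = None
        if np.ptp(x) > 0:
            spline = _fit_spline(x, y, lam=spline_lam)
        if spline is None:
            logger.warning(
                "degenerate genes-vs-UMI support; skipping spline outlier rule"
            )
        else:
            resid = y - spline(x)
            sd = resid.std()
            if sd > 0:
                z = (resid - resid.mean()) / sd
                keep[idx[np.abs(z) > outlier_z]] = False
    if not keep.any():
        raise ValueError("cell filtering removed every cell")
    return cm.cells[keep]


def filter_genes(cm: CountMatrix, min_cell_fraction: float = 0.01) -> np.ndarray:
    """Keep genes expressed in at least ``min_cell_fraction`` of cells."""
    if cm.n_cells < 1:
        raise ValueError("need at least one cell")
    n_expr = np.asarray((cm.counts > 0).sum(axis=1)).ravel()
    keep = n_expr / cm.n_cells >= min_cell_fraction
    return cm.genes[keep]


def compute_reference(cm: CountMatrix) -> np.ndarray:
    """Per-gene reference: geometric mean of counts over expressing cells.

    NaN marks genes with no expressing cell (no reference defined).
    """
    X = cm.counts.tocsr()
    nnz = np.diff(X.indptr)
    logX = X.copy()
    logX.data = np.log(logX.data)
    logsum = np.asarray(logX.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        ref = np.exp(logsum / nnz)
    ref[nnz == 0] = np.nan
    return ref


def normalize_sparse_mor(
    cm: CountMatrix, reference: np.ndarray | None = None
) -> NormalizedMatrix:
    """Sparsity-modified median-of-ratios normalization.

    size_factor(cell) = median over the genes the cell expresses (and that
    have a reference) of count / reference(gene); values are
    log2(count / size_factor + 1), so zero counts stay exactly zero.
    A precomputed ``reference`` may be supplied (e.g. from a baseline
    sample); by default it is recomputed from ``cm``.
    """
    ref = compute_reference(cm) if reference is None else np.asarray(reference, float)
    if len(ref) != cm.n_genes:
        raise ValueError("reference length must equal the number of genes")
    log_ref = np.log(ref)
    C = cm.counts.tocsc()
    size_factors = np.empty(cm.n_cells)
    data_log = np.log(C.data)
    for c in range(cm.n_cells):
        lo, hi = C.indptr[c], C.indptr[c + 1]
        rows = C.indices[lo:hi]
        ratios = data_log[lo:hi] - log_ref[rows]
        ratios = ratios[np.isfinite(ratios)]
        if ratios.size == 0:
            raise ValueError(
                f"cell {cm.cells[c]!r} has no expressed gene with a reference"
            )
        size_factors[c] = np.exp(np.median(ratios))
    values = C.copy().astype(float)
    cell_of = np.repeat(np.arange(cm.n_cells), np.diff(C.indptr))
    values.data = np.log2(values.data / size_factors[cell_of] + 1.0)
    return NormalizedMatrix(
        genes=cm.genes.copy(),
        cells=cm.cells.copy(),
        values=values.tocsr(),
        size_factors=size_factors,
    )


def select_hvg(
    nm: NormalizedMatrix,
    outlier_z: float = 3.0,
    max_iter: int = 100,
    spline_lam: float | None = None,
) -> np.ndarray:
    """Iterative spline selection of highly variable genes.

    Repeatedly fits log2 variance ~ spline(log2 mean) over retained genes,
    removes |z| > ``outlier_z`` residual outliers, and accumulates the
    positive-residual ones as HVGs until no outliers remain.
    """
    X = nm.values.tocsr()
    n_cells = X.shape[1]
    mean = np.asarray(X.sum(axis=1)).ravel() / n_cells
    sq = X.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.sum(axis=1)).ravel() / n_cells
    var = np.maximum(ex2 - mean**2, 0.0)
    usable = (mean > 0) & (var > 0)
    if int(usable.sum()) < 10:
        raise ValueError("need at least 10 genes with nonzero variance")
    gene_idx = np.nonzero(usable)[0]
    x = np.log2(mean[gene_idx])
    y = np.log2(var[gene_idx])
    retained = np.ones(len(gene_idx), dtype=bool)
    hvg = np.zeros(len(gene_idx), dtype=bool)
    for _ in range(max_iter):
        spline = _fit_spline(x[retained], y[retained], lam=spline_lam)
        if spline is None:
            raise ValueError("insufficient distinct support for the spline fit")
        resid = y[retained] - spline(x[retained])
        sd = resid.std()
        if sd == 0:
            break
        z = (resid - resid.mean()) / sd
        out = np.abs(z) > outlier_z
        if not out.any():
            break
        ridx = np.nonzero(retained)[0]
        hvg[ridx[out & (resid > 0)]] = True
        retained[ridx[out]] = False
    return nm.genes[gene_idx[hvg]]


def knee_point(values: Sequence[float]) -> int:
    """Elbow of a decreasing criterion curve, 1-based.

    Returns the k maximizing the perpendicular distance from (k, value_k)
    to the chord joining the first and last points; ties break toward
    smaller k. A constant series yields k = 1 with a warning.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least three values")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    K = len(v)
    if np.ptp(v) == 0:
        logger.warning("constant criterion series; knee point defaults to k=1")
        return 1
    k = np.arange(1, K + 1, dtype=float)
    # |cross product| of (chord, point - start); chord norm is k-independent
    num = np.abs((K - 1) * (v - v[0]) - (v[-1] - v[0]) * (k - 1))
    return int(np.argmax(num)) + 1
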