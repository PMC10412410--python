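"""Normalization, highly variable gene selection and the PCA embedding.

The workflow is the standard log-normalize / HVG / scale / PCA stack of
droplet scRNA-seq analysis:

* ``normalize`` — library-size normalization to a fixed scale factor
  followed by log1p, so each cell's profile is invariant to its sequencing
  depth.
* ``select_hvgs`` — rank genes by variability.  The default score fits a
  lowess trend of log variance against log mean and ranks genes by the
  residual, so that genes more variable than expected at their expression
  level come out on top; a plain dispersion (variance / mean) score is also
  available.  Calling this on a cluster subset is exactly how features are
  re-derived for reclustering: variability is scored on the provided matrix
  only.
* ``compute_embedding`` — per-gene z-scoring (clipped at +/-10 to bound
  outlier leverage) of the HVG submatrix, then PCA.  Deterministic for a
  fixed seed.

All functions treat cells as rows and preserve cell order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import DomainError, ParameterError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["NormalizedMatrix", "HVGSet", "Embedding",
           "normalize", "select_hvgs", "compute_embedding"]


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, cells x genes, sparse, zeros preserved."""

    matrix: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]


@dataclass
class HVGSet:
    """Highly variable genes ordered by decreasing variability score."""

    gene_ids: np.ndarray
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class Embedding:
    """Cells x d coordinates (PCA space); cell order matches the source."""

    coords: np.ndarray
    cell_ids: np.ndarray
    explained_variance_ratio: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2:
            raise ParameterError("embedding coordinates must be 2-D")
        if not np.all(np.isfinite(self.coords)):
            raise DomainError("embedding contains non-finite coordinates")
        if len(self.cell_ids) != self.coords.shape[0]:
            raise ParameterError("cell_ids length != number of rows")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


def normalize(
    counts: ExpressionMatrix,
    scale_factor: float = 1e4,
    on_zero_cells: str = "drop",
) -> NormalizedMatrix:
    """Library-size normalize and log-transform raw counts.

    Each entry becomes ``log(1 + scale_factor * count / cell_total)``;
    zeros stay zero, and multiplying a cell's counts by any positive
    constant leaves its normalized vector unchanged.

    ``on_zero_cells`` controls cells whose total count is zero: ``"drop"``
    removes them with a warning, ``"error"`` raises.
    """
    if scale_factor <= 0:
        raise ParameterError("scale_factor must be positive")
    if on_zero_cells not in ("drop", "error"):
        raise ParameterError("on_zero_cells must be 'drop' or 'error'")
    totals = np.asarray(counts.counts.sum(axis=1)).ravel()
    zero = totals == 0
    cell_ids = counts.cell_ids
    mat = counts.counts
    if zero.any():
        if on_zero_cells == "error":
            raise DomainError(
                f"{int(zero.sum())} cell(s) with zero total counts "
                f"(first: {cell_ids[zero][0]!r})"
            )
        logger.warning("dropping %d all-zero cell(s)", int(zero.sum()))
        keep = ~zero
        mat, cell_ids, totals = mat[keep], cell_ids[keep], totals[keep]
    norm = sp.csr_matrix(mat, dtype=np.float64, copy=True)
    # scale nonzero entries row-wise, then log1p; sparsity is preserved
    row_scale = scale_factor / totals
    norm.data *= np.repeat(row_scale, np.diff(norm.indptr))
    np.log1p(norm.data, out=norm.data)
    return NormalizedMatrix(norm, cell_ids, counts.gene_ids)


def _gene_moments(matrix: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    n = matrix.shape[0]
    mean = np.asarray(matrix.mean(axis=0)).ravel()
    sq = np.asarray(matrix.multiply(matrix).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    return mean, np.maximum(var, 0.0)


def select_hvgs(
    norm: NormalizedMatrix,
    n_hvgs: int = 2000,
    method: str = "vst_like",
) -> HVGSet:
    """Rank genes by variability and return the top ``n_hvgs``.

    ``vst_like`` scores each gene by the residual of log10 variance around
    a lowess trend in log10 mean, standardized by the residual spread, so
    the score is mean-corrected.  ``dispersion`` scores by variance / mean.
    Genes with zero variance always rank last (score ``-inf``).
    """
    if n_hvgs <= 0:
        raise ParameterError("n_hvgs must be positive")
    if n_hvgs > norm.n_genes:
        raise ParameterError(
            f"n_hvgs={n_hvgs} exceeds the {norm.n_genes} genes available"
        )
    mean, var = _gene_moments(norm.matrix)
    expressed = (mean > 0) & (var > 0)
    scores = np.full(norm.n_genes, -np.inf)
    if method == "vst_like":
        if expressed.sum() >= 10:
            lm = np.log10(mean[expressed])
            lv = np.log10(var[expressed])
            trend = lowess(lv, lm, frac=0.3, return_sorted=False)
            resid = lv - trend
            sd = resid.std()
            scores[expressed] = resid / sd if sd > 0 else resid
        else:  # too few genes for a trend; fall back to raw variance
            scores[expressed] = var[expressed]
    elif method == "dispersion":
        # classic dispersion is defined on the de-logged scale
        lin = norm.matrix.copy()
        lin.data = np.expm1(lin.data)
        lmean, lvar = _gene_moments(lin)
        ok = expressed & (lmean > 0)
        scores[ok] = lvar[ok] / lmean[ok]
    else:
        raise ParameterError(f"unknown HVG method {method!r}")
    # stable ranking: score desc, then gene order for ties
    order = np.lexsort((np.arange(norm.n_genes), -scores))[:n_hvgs]
    return HVGSet(norm.gene_ids[order], scores[order])


def compute_embedding(
    norm: NormalizedMatrix,
    hvgs: HVGSet,
    n_pcs: int = 30,
    seed: int = 0,
    clip: float = 10.0,
) -> Embedding:
    """Z-score the HVG submatrix (clipped at ``+/-clip``) and run PCA."""
    if n_pcs < 2:
        raise ParameterError("n_pcs must be >= 2")
    if n_pcs >= min(norm.n_cells, len(hvgs)):
        raise ParameterError(
            f"n_pcs={n_pcs} must be < min(n_cells={norm.n_cells}, "
            f"n_hvgs={len(hvgs)})"
        )
    col = {g: i for i, g in enumerate(norm.gene_ids)}
    idx = np.array([col[g] for g in hvgs.gene_ids])
    x = np.asarray(norm.matrix[:, idx].todense(), dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = np.clip((x - mu) / sd, -clip, clip)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(x)
    return Embedding(coords, norm.cell_ids, pca.explained_variance_ratio_)
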