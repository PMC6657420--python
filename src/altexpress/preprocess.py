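"""Normalization, covariate regression, and feature selection.

Bulk counts are normalized with a variance-stabilizing transform
approximated by median-library scaling followed by log2(x + 1); single-cell
counts use the standard global-scaling log-normalization
ln(1 + scale * count / cell_total).  Confounders such as per-cell molecule
counts or cell-cycle scores are removed by per-gene ordinary least squares.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import COUNTS, NORMALIZED, RESIDUALS, ConfigError, ExpressionMatrix

logger = logging.getLogger(__name__)


def normalize_counts(
    counts: ExpressionMatrix, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Median-library scaling + log2(x + pseudocount).

    Each sample's counts are rescaled to the median library size, then log
    transformed.  Monotone per sample; a sample whose counts are a scalar
    multiple of another normalizes to the same column.
    """
    if counts.units != COUNTS:
        raise ConfigError(
            f"normalize_counts expects raw counts, got units={counts.units!r}"
        )
    arr = counts.values.to_numpy(dtype=np.float64)
    if (arr < 0).any():
        raise ValueError("negative counts encountered")
    lib = arr.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"all-zero sample(s): {list(counts.samples[zero[:5]])}"
        )
    scaled = arr * (np.median(lib) / lib)
    out = pd.DataFrame(
        np.log2(scaled + pseudocount), index=counts.genes, columns=counts.samples
    )
    return ExpressionMatrix(out, NORMALIZED)


def normalize_single_cell(
    counts: ExpressionMatrix, scale: float = 10_000.0
) -> ExpressionMatrix:
    """Global-scaling log-normalization: ln(1 + scale * count / cell_total).

    Cells with zero total are dropped with a warning reporting the count.
    """
    if counts.units != COUNTS:
        raise ConfigError(
            f"normalize_single_cell expects raw counts, got units={counts.units!r}"
        )
    arr = counts.values.to_numpy(dtype=np.float64)
    totals = arr.sum(axis=0)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d empty cell(s) with zero total counts", n_dropped)
        arr = arr[:, keep]
        totals = totals[keep]
    out = pd.DataFrame(
        np.log1p(scale * arr / totals),
        index=counts.genes,
        columns=counts.samples[keep],
    )
    return ExpressionMatrix(out, NORMALIZED)


def regress_covariates(
    expr: ExpressionMatrix, covariates: pd.DataFrame
) -> ExpressionMatrix:
    """Per-gene OLS residuals of expression on covariates plus intercept.

    ``covariates`` is samples x k, aligned to ``expr.samples``.  Residuals
    are orthogonal to every covariate column.  Rank-deficient designs
    (including zero-variance covariates) raise.
    """
    cov = covariates.reindex(expr.samples)
    if cov.isna().any().any():
        raise ConfigError("covariates missing for some samples")
    n = expr.n_samples
    X = np.column_stack([np.ones(n), cov.to_numpy(dtype=np.float64)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigError("covariate design matrix is rank-deficient")
    Y = expr.values.to_numpy(dtype=np.float64).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    out = pd.DataFrame(resid, index=expr.genes, columns=expr.samples)
    return ExpressionMatrix(out, RESIDUALS)


def select_top_variance(expr: ExpressionMatrix, k: int = 10_000) -> ExpressionMatrix:
    """Keep the min(k, n_genes) genes with largest variance across samples.

    Ties are broken by gene identifier (lexicographic) so the selection is
    deterministic; selected genes keep their original row order.
    """
    if expr.n_genes <= k:
        return expr.copy()
    var = expr.values.var(axis=1, ddof=0)
    ranking = sorted(zip(-var.to_numpy(), expr.genes))
    chosen = {g for _, g in ranking[:k]}
    keep = [g for g in expr.genes if g in chosen]
    return ExpressionMatrix(expr.values.loc[keep], expr.units)
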