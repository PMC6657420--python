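"""Gene aggregation: regulon activity scores and robust cluster averages.

Two ways of collapsing thousands of gene-level variables into a smaller
set of aggregate variables that are more robust to per-gene noise:

* **Regulon activity** — each transcription factor's signed target set is
  summarized, per sample, by the mean of the targets' z-scored expression
  (signature), sign-corrected by each target's regulation mode and scaled
  by sqrt(n_targets).  Under a null of independent unit-variance target
  signatures the score has variance ~1 whatever the regulon size, so
  activities are comparable across regulons.  This is a rank-free analogue
  of master-regulator activity inference: it reports the collective
  expression change of the TF-centered network relative to the dataset
  mean of each gene.

* **Robust cluster averages** — disjoint coexpression clusters (found by
  correlation-distance hierarchical clustering, or supplied externally)
  are collapsed with a one-step Tukey biweight, a robust location estimate
  that zero-weights outliers more than ``c`` rescaled MADs from the
  median.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ConfigError, ExpressionMatrix, GeneCluster, Regulon

logger = logging.getLogger(__name__)


def build_signature(expr: ExpressionMatrix) -> pd.DataFrame:
    """Z-score each gene across samples (population SD, divisor n).

    Genes with zero SD get an all-zero signature row.  Requires >= 3
    samples for the SD to be meaningful.
    """
    if expr.n_samples < 3:
        raise ConfigError(
            f"signature needs >= 3 samples, got {expr.n_samples}"
        )
    arr = expr.values.to_numpy(dtype=np.float64)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[np.repeat(sd == 0, arr.shape[1], axis=1)] = 0.0
    return pd.DataFrame(z, index=expr.genes, columns=expr.samples)


def regulon_activity(
    signature: pd.DataFrame, regulons: list[Regulon], min_targets: int = 10
) -> pd.DataFrame:
    """Regulon x sample activity: sqrt(n) * mean(mode * target signature).

    Regulons with fewer than ``min_targets`` usable targets (present in
    the signature) are dropped with a warning; if none survive, raises.
    """
    gene_pos = {g: i for i, g in enumerate(signature.index)}
    sig = signature.to_numpy(dtype=np.float64)
    rows = {}
    for reg in regulons:
        usable = [(gene_pos[g], m) for g, m in reg.targets.items() if g in gene_pos]
        if len(usable) < min_targets:
            logger.warning(
                "regulon %s: only %d of %d targets present (< %d); dropped",
                reg.tf, len(usable), reg.size, min_targets,
            )
            continue
        idx = np.array([i for i, _ in usable])
        modes = np.array([m for _, m in usable], dtype=np.float64)
        n = len(usable)
        rows[reg.tf] = np.sqrt(n) * (modes[:, None] * sig[idx]).mean(axis=0)
    if not rows:
        raise ConfigError("no regulon has enough targets in the signature")
    return pd.DataFrame(rows, index=signature.columns).T


def tukey_biweight(values, c: float = 5.0, eps: float = 1e-4) -> float:
    """One-step Tukey biweight robust location estimate.

    With M = median and S = median absolute deviation, each point gets
    weight (1 - u^2)^2 for u = (x - M)/(c*S + eps) when |u| < 1, else 0;
    the result is the weighted mean.  Falls back to the median if every
    weight is zero.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("tukey_biweight requires at least one finite value")
    m = np.median(x)
    s = np.median(np.abs(x - m))
    u = (x - m) / (c * s + eps)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    total = w.sum()
    if total == 0:
        return float(m)
    return float((w * x).sum() / total)


def cluster_genes(
    expr: ExpressionMatrix, min_size: int = 10
) -> list[GeneCluster]:
    """Disjoint coexpression clusters of size >= min_size.

    Average-linkage hierarchical clustering on (1 - Pearson r) distance;
    the tree is cut at the height that maximizes the number of clusters of
    size >= min_size (lowest such height on ties).  Genes in undersized
    clusters are left out (an implicit "unclustered" bin excluded from
    aggregation).  Constant genes cannot carry correlation and are
    excluded up front; an all-constant matrix raises.
    """
    if expr.n_genes < min_size:
        raise ConfigError(
            f"need >= {min_size} genes to cluster, got {expr.n_genes}"
        )
    arr = expr.values.to_numpy(dtype=np.float64)
    sd = arr.std(axis=1, ddof=0)
    varying = sd > 0
    if varying.sum() < min_size:
        raise ConfigError("matrix is (almost) constant; nothing to cluster")
    genes = expr.genes[varying]
    corr = np.corrcoef(arr[varying])
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")

    # choose the cut height maximizing the number of clusters of size
    # >= min_size; ties broken by most genes covered, then lowest height
    heights = np.unique(Z[:, 2])
    best_key, best_labels = (0, 0), None
    for h in heights:
        labels = fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(labels)
        big = sizes[1:] >= min_size
        key = (int(big.sum()), int(sizes[1:][big].sum()))
        if key > best_key:
            best_key, best_labels = key, labels
    if best_labels is None:
        return []
    labels = best_labels
    clusters = []
    for lab in np.unique(labels):
        members = [g for g, l in zip(genes, labels) if l == lab]
        if len(members) >= min_size:
            clusters.append(GeneCluster(f"C{len(clusters):02d}", sorted(members)))
    return clusters


def aggregate_clusters(
    expr: ExpressionMatrix, clusters: list[GeneCluster]
) -> pd.DataFrame:
    """Cluster x sample matrix of Tukey-biweight averages."""
    missing = {
        g for cl in clusters for g in cl.members if g not in expr.values.index
    }
    if missing:
        raise ConfigError(
            f"clusters reference unknown gene(s): {sorted(missing)[:5]}"
        )
    rows = {}
    for cl in clusters:
        block = expr.values.loc[cl.members].to_numpy(dtype=np.float64)
        rows[cl.cluster_id] = [
            tukey_biweight(block[:, j]) for j in range(block.shape[1])
        ]
    return pd.DataFrame(rows, index=expr.samples).T
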