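"""AUROC computation, paired model comparison, robustness curves."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, wilcoxon

from .containers import ConfigError


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank formulation.

    Equals the fraction of (positive, negative) pairs where the positive
    outscores the negative, with ties worth half a pair — identical to the
    trapezoidal area under the ROC curve.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.isfinite(s).all():
        raise ValueError("scores contain non-finite values")
    pos = y == 1
    n_pos = int(pos.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ConfigError("AUROC needs both classes present")
    ranks = rankdata(s)  # average ranks handle ties -> half credit
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def paired_wilcoxon(auroc_a, auroc_b) -> tuple[float, int]:
    """Two-tailed Wilcoxon signed-rank test on paired AUROC vectors.

    Returns (p-value, direction) where direction is the sign of the median
    paired difference (a - b).  Zero differences are dropped; if all
    differences are zero the result is (1.0, 0).  The exact null
    distribution is used for <= 25 informative pairs, the normal
    approximation with continuity correction above that.
    """
    a = np.asarray(auroc_a, dtype=np.float64)
    b = np.asarray(auroc_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = a - b
    nz = diff[diff != 0]
    if nz.size == 0:
        return 1.0, 0
    method = "exact" if nz.size <= 25 else "approx"
    res = wilcoxon(nz, alternative="two-sided", method=method, correction=True)
    direction = int(np.sign(np.median(diff)))
    return float(res.pvalue), direction


def robustness_curve(results: pd.DataFrame) -> pd.DataFrame:
    """Summarize per-rep AUROCs into a (level, mode) robustness table.

    ``results`` needs columns ``level``, ``mode``, ``auroc`` (one row per
    rep).  Returns one row per (level, mode) with mean AUROC, SD of the
    AUROC distribution (0 when n = 1) and n, levels sorted ascending.
    """
    required = {"level", "mode", "auroc"}
    if results is None or len(results) == 0:
        raise ConfigError("robustness_curve requires non-empty results")
    missing = required - set(results.columns)
    if missing:
        raise ConfigError(f"results missing columns: {sorted(missing)}")
    rows = []
    for (level, mode), grp in results.groupby(["level", "mode"]):
        vals = grp["auroc"].to_numpy(dtype=np.float64)
        rows.append(
            {
                "level": level,
                "mode": mode,
                "mean_auroc": float(vals.mean()),
                "sd_auroc": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["level", "mode"], kind="stable")
        .reset_index(drop=True)
    )


def plot_robustness_curve(curve: pd.DataFrame, path: str) -> None:
    """Write a robustness curve (mean +/- SD AUROC vs level) to SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for mode, grp in curve.groupby("mode"):
        ax.errorbar(
            grp["level"], grp["mean_auroc"], yerr=grp["sd_auroc"],
            marker="o", capsize=3, label=str(mode),
        )
    ax.axhline(0.5, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("perturbation level")
    ax.set_ylabel("AUROC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
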