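"""Per-mutation classification benchmark on single cells.

Mirrors the shape of a pooled CRISPR screen with single-cell readout:
cells carry exactly one guide (targeting a gene, or a non-targeting
control); for each targeted gene, a binary contrast of that gene's cells
versus control cells is classified from (a) normalized gene expression and
(b) regulon-activity features, with identical train/test splits so the
two feature modes are paired rep-by-rep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import build_signature, regulon_activity
from .containers import ConfigError, ExpressionMatrix, Regulon
from .evaluation import paired_wilcoxon
from .modeling import ModelSpec, repeated_evaluation

logger = logging.getLogger(__name__)


def build_mutation_contrasts(
    cells: ExpressionMatrix,
    guide_assignments: pd.Series,
    control_label: str = "CTRL",
) -> list[tuple[str, pd.Series]]:
    """One binary contrast per targeted gene: its cells vs control cells.

    ``guide_assignments`` maps cell id -> targeted gene (or the control
    label).  Cells carrying guides for other genes are excluded from each
    contrast.  Returns (event_id, labels) pairs where labels is a 0/1
    Series over the contrast's cells.
    """
    guides = guide_assignments.reindex(cells.samples)
    if guides.isna().any():
        missing = list(cells.samples[guides.isna()][:5])
        raise ConfigError(f"cells missing guide assignment: {missing}")
    control_cells = guides.index[guides == control_label]
    if control_cells.empty:
        raise ConfigError(f"no control cells labelled {control_label!r}")
    targets = sorted(set(guides.unique()) - {control_label})
    if not targets:
        raise ConfigError("no targeted genes in guide assignments")
    contrasts = []
    for gene in targets:
        pos = guides.index[guides == gene]
        labels = pd.Series(
            np.r_[np.ones(len(pos), dtype=int), np.zeros(len(control_cells), dtype=int)],
            index=pos.append(control_cells),
        )
        contrasts.append((f"{gene}:mutation", labels))
    return contrasts


@dataclass
class CropSeqResult:
    """Per-event paired AUROCs for the two feature modes, plus pooled test."""

    table: pd.DataFrame  # event_id, mode, mean_auroc, sd_auroc, n_reps
    per_rep: pd.DataFrame  # event_id, rep, auroc_expression, auroc_activity
    pooled_p: float
    pooled_direction: int


def run_crop_seq_benchmark(
    cells: ExpressionMatrix,
    guide_assignments: pd.Series,
    regulons: list[Regulon],
    spec: ModelSpec,
    reps: int = 100,
    min_cells: int = 10,
    control_label: str = "CTRL",
) -> CropSeqResult:
    """Paired expression-vs-activity benchmark over all guide contrasts.

    ``cells`` should be normalized (and covariate-regressed) already.  For
    each contrast the same split seeds drive both feature modes, so the
    AUROC pairs are comparable rep-by-rep; the pooled two-tailed Wilcoxon
    signed-rank test aggregates activity-minus-expression differences over
    every (event, rep) pair.  Contrasts with fewer than ``min_cells``
    cells in either class are skipped with a warning.
    """
    contrasts = build_mutation_contrasts(cells, guide_assignments, control_label)
    rows, per_rep_rows = [], []
    pooled_expr, pooled_act = [], []
    for eid, labels in contrasts:
        n_pos = int(labels.sum())
        n_neg = int((1 - labels).sum())
        if min(n_pos, n_neg) < min_cells:
            logger.warning(
                "contrast %s skipped: %d positive / %d control cells (< %d)",
                eid, n_pos, n_neg, min_cells,
            )
            continue
        sub = ExpressionMatrix(cells.values[labels.index], cells.units)
        expr_features = sub.values
        activity = regulon_activity(build_signature(sub), regulons)
        dist_e = repeated_evaluation(expr_features, labels, spec, reps, eid)
        dist_a = repeated_evaluation(activity, labels, spec, reps, eid)
        n_pairs = min(dist_e.aurocs.size, dist_a.aurocs.size)
        pooled_expr.extend(dist_e.aurocs[:n_pairs])
        pooled_act.extend(dist_a.aurocs[:n_pairs])
        for rep in range(n_pairs):
            per_rep_rows.append(
                {
                    "event_id": eid,
                    "rep": rep,
                    "auroc_expression": dist_e.aurocs[rep],
                    "auroc_activity": dist_a.aurocs[rep],
                }
            )
        for mode, dist in (("expression", dist_e), ("activity", dist_a)):
            rows.append(
                {
                    "event_id": eid,
                    "mode": mode,
                    "mean_auroc": dist.mean,
                    "sd_auroc": dist.sd,
                    "n_reps": dist.aurocs.size,
                }
            )
    if not rows:
        raise ConfigError("no contrast had enough cells to benchmark")
    pooled_p, direction = paired_wilcoxon(pooled_act, pooled_expr)
    return CropSeqResult(
        table=pd.DataFrame(rows),
        per_rep=pd.DataFrame(per_rep_rows),
        pooled_p=pooled_p,
        pooled_direction=direction,
    )
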