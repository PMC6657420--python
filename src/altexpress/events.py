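"""Turn mutation and copy-number tables into binary event matrices.

The classifiers consume a gene-event x sample binary matrix.  This module
applies the preprocessing rules used throughout the analysis:

* every gene receives the log2 ratio of the segment that overlaps it the
  most (:func:`assign_gene_cnv`); genes no segment touches are neutral (0);
* amplification / deletion calls use a symmetric |log2| >= 0.5 threshold
  (:func:`binarize_cnv`), roughly one copy gained or lost;
* silent mutation classes are discarded before collapsing a MAF-style
  table to binary gene x sample presence (:func:`filter_silent_mutations`);
* events are kept for modeling only when carried by 5-95% of samples and
  by at least 10 samples (:func:`filter_events`);
* samples in which more than 0.5% of genome genes are altered are flagged
  hypermodified (:func:`flag_hypermodified`) but never removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    CnvSegment,
    ConfigError,
    EventMatrix,
    GeneInterval,
    SchemaError,
    event_id,
    parse_event_id,
)

#: MAF variant classifications with no protein-sequence consequence.
SILENT_CLASSES = frozenset(
    {"Silent", "3'UTR", "5'UTR", "Intron", "IGR", "3'Flank", "5'Flank", "RNA"}
)


def assign_gene_cnv(
    segments: list[CnvSegment], genes: list[GeneInterval]
) -> pd.DataFrame:
    """Per-gene log2 ratio from the maximally overlapping segment.

    For each (gene, sample), the value is the ``log2_ratio`` of the segment
    with the largest base-pair overlap with the gene interval.  Overlap
    ties are broken by larger ``|log2_ratio|``, then by leftmost segment
    start.  Genes overlapping no segment in a sample get 0 (neutral).

    Returns a genes x samples DataFrame (gene order preserved).
    """
    sample_ids = sorted({s.sample_id for s in segments})
    out = pd.DataFrame(
        0.0, index=[g.gene_id for g in genes], columns=sample_ids
    )
    by_sample_chrom: dict[tuple[str, str], list[CnvSegment]] = {}
    for seg in segments:
        by_sample_chrom.setdefault((seg.sample_id, seg.chrom), []).append(seg)

    for (sid, chrom), segs in by_sample_chrom.items():
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        ratios = np.array([s.log2_ratio for s in segs])
        for g in genes:
            if g.chrom != chrom:
                continue
            overlap = np.minimum(ends, g.end) - np.maximum(starts, g.start)
            overlap = np.clip(overlap, 0, None)
            if overlap.max() == 0:
                continue
            # max overlap, then max |log2|, then leftmost start
            order = np.lexsort((starts, -np.abs(ratios), -overlap))
            out.at[g.gene_id, sid] = ratios[order[0]]
    return out


def binarize_cnv(
    cnv: pd.DataFrame, threshold: float = 0.5
) -> tuple[EventMatrix, EventMatrix]:
    """Split a gene x sample log2 matrix into amplification and deletion calls.

    Amplification: value >= +threshold; deletion: value <= -threshold
    (both inclusive).  Returns two EventMatrix blocks covering every gene.
    """
    if threshold <= 0:
        raise ConfigError(f"threshold must be > 0, got {threshold}")
    arr = cnv.to_numpy()
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))
        cells = [(cnv.index[i], cnv.columns[j]) for i, j in bad[:10]]
        raise ValueError(f"non-finite CNV values at cells {cells}")
    amp = pd.DataFrame(
        (arr >= threshold).astype(np.int8),
        index=[event_id(g, "amplification") for g in cnv.index],
        columns=cnv.columns,
    )
    dele = pd.DataFrame(
        (arr <= -threshold).astype(np.int8),
        index=[event_id(g, "deletion") for g in cnv.index],
        columns=cnv.columns,
    )
    return EventMatrix(amp), EventMatrix(dele)


def filter_silent_mutations(
    maf: pd.DataFrame,
    samples: list[str] | None = None,
    blacklist: set[str] | None = None,
) -> EventMatrix:
    """Collapse a MAF-style table to a binary mutation EventMatrix.

    Rows whose ``Variant_Classification`` has no protein consequence are
    discarded, as are genes in the optional blacklist; the remainder is
    collapsed to gene x sample presence/absence.  ``samples`` fixes the
    column universe (samples with no surviving mutation get all-zero
    columns); by default the columns are the samples seen in the table.
    """
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    missing = required - set(maf.columns)
    if missing:
        raise SchemaError(f"mutation table missing columns: {sorted(missing)}")
    keep = maf[~maf["Variant_Classification"].isin(SILENT_CLASSES)]
    if blacklist:
        keep = keep[~keep["Hugo_Symbol"].isin(blacklist)]
    if samples is None:
        samples = sorted(maf["Tumor_Sample_Barcode"].unique())
    if keep.empty:
        return EventMatrix(
            pd.DataFrame(index=pd.Index([]), columns=pd.Index(samples), dtype=np.int8)
        )
    present = (
        keep.assign(v=1)
        .pivot_table(
            index="Hugo_Symbol", columns="Tumor_Sample_Barcode", values="v",
            aggfunc="max", fill_value=0,
        )
        .reindex(columns=samples, fill_value=0)
    )
    present.index = [event_id(g, "mutation") for g in present.index]
    return EventMatrix(present.astype(np.int8))


def filter_events(
    events: EventMatrix,
    min_frac: float = 0.05,
    max_frac: float = 0.95,
    min_count: int = 10,
) -> EventMatrix:
    """Keep events carried by min_frac-max_frac of samples and >= min_count.

    All boundaries are inclusive.  Idempotent: filtering a filtered matrix
    changes nothing.
    """
    if min_frac >= max_frac:
        raise ConfigError(
            f"min_frac ({min_frac}) must be below max_frac ({max_frac})"
        )
    if events.n_events == 0:
        raise ConfigError("filter_events requires a non-empty EventMatrix")
    freq = events.frequency()
    keep = (
        (freq["carrier_fraction"] >= min_frac)
        & (freq["carrier_fraction"] <= max_frac)
        & (freq["carrier_count"] >= min_count)
    )
    return EventMatrix(events.values.loc[keep.to_numpy()])


def flag_hypermodified(
    events: EventMatrix, genome_size: int, frac: float = 0.005
) -> pd.Series:
    """Flag samples where > frac of genome genes carry any alteration.

    The flag is reported only; samples are never removed.  A gene counts
    once per sample no matter how many event classes hit it.
    """
    if genome_size <= 0:
        raise ConfigError(f"genome_size must be positive, got {genome_size}")
    genes = [parse_event_id(e)[0] for e in events.events]
    n_distinct = len(set(genes))
    if genome_size < n_distinct:
        raise ConfigError(
            f"genome_size {genome_size} below the {n_distinct} distinct "
            "genes present in the event matrix"
        )
    altered = (
        pd.DataFrame(events.values.to_numpy(), index=genes, columns=events.samples)
        .groupby(level=0)
        .max()
        .sum(axis=0)
    )
    return (altered / genome_size) > frac
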