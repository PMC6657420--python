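"""Readers and writers for the interchange formats.

TSV is the canonical matrix format (genes x samples, header row of sample
identifiers); MatrixMarket (MTX) with sidecar ``<stem>.genes.txt`` /
``<stem>.samples.txt`` name files serves large sparse single-cell
matrices.  Segment tables use SEG (tab-separated, 1-based inclusive start
on disk, converted to the package's 0-based half-open convention on read),
gene models use BED (already 0-based half-open), mutations use a minimal
MAF, regulons and clusters use simple 3- and 2-column TSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .containers import (
    CnvSegment,
    EventMatrix,
    ExpressionMatrix,
    GeneInterval,
    Regulon,
    SchemaError,
)

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]
MAF_COLUMNS = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]


# ---------------------------------------------------------------- matrices

def write_matrix(expr: ExpressionMatrix, path: str | Path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        expr.values.to_csv(path, sep="\t", index_label="gene")
    elif fmt == "mtx":
        stem = path.with_suffix("")
        spio.mmwrite(str(path), sp.csr_matrix(expr.values.to_numpy()))
        stem.with_suffix(".genes.txt").write_text("\n".join(expr.genes) + "\n")
        stem.with_suffix(".samples.txt").write_text("\n".join(expr.samples) + "\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_matrix(path: str | Path, fmt: str = "tsv", units: str = "counts") -> ExpressionMatrix:
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = None
    elif fmt == "mtx":
        stem = path.with_suffix("")
        mat = sp.csr_matrix(spio.mmread(str(path))).toarray()
        genes = stem.with_suffix(".genes.txt").read_text().splitlines()
        samples = stem.with_suffix(".samples.txt").read_text().splitlines()
        if mat.shape != (len(genes), len(samples)):
            raise SchemaError(
                f"{path}: matrix shape {mat.shape} does not match sidecar names "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    dupes = df.index[df.index.duplicated()].unique()
    if len(dupes):
        raise SchemaError(f"{path}: duplicate gene identifier(s): {list(dupes[:5])}")
    return ExpressionMatrix(df, units)


# ------------------------------------------------------------------ events

def write_events(events: EventMatrix, path: str | Path) -> None:
    events.values.to_csv(path, sep="\t", index_label="event_id")


def read_events(path: str | Path) -> EventMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return EventMatrix(df)


# --------------------------------------------------------------------- SEG

def write_seg(segments: list[CnvSegment], path: str | Path) -> None:
    """SEG on disk is 1-based inclusive-start; internal is 0-based half-open."""
    rows = [
        {
            "Sample": s.sample_id,
            "Chromosome": s.chrom,
            "Start": s.start + 1,
            "End": s.end,
            "Num_Probes": max((s.end - s.start) // 1000, 1),
            "Segment_Mean": s.log2_ratio,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> list[CnvSegment]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS[:4] + ["Segment_Mean"]) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: SEG missing columns {sorted(missing)}")
    segments = []
    for i, row in df.iterrows():
        try:
            segments.append(
                CnvSegment(
                    str(row["Sample"]),
                    str(row["Chromosome"]),
                    int(row["Start"]) - 1,
                    int(row["End"]),
                    float(row["Segment_Mean"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: line {i + 2}: {exc}") from exc
    return segments


# --------------------------------------------------------------------- MAF

def write_maf(maf: pd.DataFrame, path: str | Path) -> None:
    maf[MAF_COLUMNS].to_csv(path, sep="\t", index=False)


def read_maf(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MAF_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: MAF missing columns {sorted(missing)}")
    return df


# --------------------------------------------------------------------- BED

def write_bed(genes: list[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def read_bed(path: str | Path) -> list[GeneInterval]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise SchemaError(f"{path}: line {ln}: need 4 BED columns")
            try:
                genes.append(
                    GeneInterval(parts[3], parts[0], int(parts[1]), int(parts[2]))
                )
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{path}: line {ln}: {exc}") from exc
    return genes


# ---------------------------------------------------------- regulons, clusters

def write_regulons(regulons: list[Regulon], path: str | Path) -> None:
    rows = [
        {"tf": r.tf, "target": g, "mode": m}
        for r in regulons
        for g, m in r.targets.items()
    ]
    pd.DataFrame(rows, columns=["tf", "target", "mode"]).to_csv(
        path, sep="\t", index=False
    )


def read_regulons(path: str | Path, min_targets: int = 10) -> list[Regulon]:
    df = pd.read_csv(path, sep="\t")
    missing = {"tf", "target", "mode"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: regulon TSV missing columns {sorted(missing)}")
    regulons = []
    for tf, grp in df.groupby("tf", sort=True):
        targets = dict(zip(grp["target"].astype(str), grp["mode"].astype(int)))
        regulons.append(Regulon(str(tf), targets, min_targets=min_targets))
    return regulons


def write_clusters(clusters, path: str | Path) -> None:
    rows = [
        {"cluster_id": c.cluster_id, "gene": g} for c in clusters for g in c.members
    ]
    pd.DataFrame(rows, columns=["cluster_id", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_clusters(path: str | Path):
    from .containers import GeneCluster

    df = pd.read_csv(path, sep="\t")
    missing = {"cluster_id", "gene"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: cluster TSV missing columns {sorted(missing)}")
    return [
        GeneCluster(str(cid), list(grp["gene"].astype(str)))
        for cid, grp in df.groupby("cluster_id", sort=True)
    ]


def read_gene_list(path: str | Path) -> set[str]:
    """One gene per line (e.g. a mutation blacklist)."""
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


# ----------------------------------------------------------------- cohorts

def write_cohort(cohort, outdir: str | Path, fmt: str = "tsv") -> None:
    """Write a simulated cohort's artifacts into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = "mtx" if fmt == "mtx" else "tsv"
    write_matrix(cohort.counts, outdir / f"counts.{suffix}", fmt)
    write_events(cohort.truth_events, outdir / "truth_events.tsv")
    write_regulons(cohort.regulons, outdir / "regulons.tsv")
    write_clusters(cohort.clusters, outdir / "clusters.tsv")
    write_bed(cohort.gene_models, outdir / "gene_models.bed")
    if cohort.segments:
        write_seg(cohort.segments, outdir / "segments.seg")
    mut_rows = []
    for eid in cohort.truth_events.events:
        gene, cls = eid.rsplit(":", 1)
        if cls != "mutation":
            continue
        carriers = cohort.truth_events.values.loc[eid]
        for s in carriers.index[carriers == 1]:
            mut_rows.append(
                {
                    "Hugo_Symbol": gene,
                    "Tumor_Sample_Barcode": s,
                    "Variant_Classification": "Missense_Mutation",
                }
            )
    if mut_rows:
        write_maf(pd.DataFrame(mut_rows), outdir / "mutations.maf")
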