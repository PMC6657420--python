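"""Synthetic cohort generator with planted regulatory signal.

Generates bulk and single-cell expression cohorts that have the
statistical structure the downstream analysis assumes:

* counts follow a negative-binomial model with gene-specific log-normal
  baseline means scaled to a target library size;
* each transcription factor (TF) drives a regulon of signed targets whose
  expression co-varies through a shared per-sample latent factor;
* *driver* alterations (mutations, amplifications, deletions) shift the
  affected regulon's targets on the log scale by a stated number of
  biological standard deviations, so effect sizes are interpretable and
  counts stay non-negative;
* *passenger* alterations are assigned to samples at the stated prevalence
  with no expression consequence;
* copy-number drivers additionally multiply the altered gene's expected
  count by the relative dosage ``2**log2_ratio``, and can be rendered as a
  SEG-style segment table;
* the single-cell mode replicates each sample into cells and thins each
  cell with the beta down-sampling engine, producing depth-dependent
  dropout.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    COUNTS,
    EVENT_CLASSES,
    CnvSegment,
    ConfigError,
    EventMatrix,
    ExpressionMatrix,
    GeneCluster,
    GeneInterval,
    Regulon,
    event_id,
)
from .perturb import DownsampleConfig, downsample_counts

# Synthetic genome layout: one chromosome per 1,000 genes, 1 kb genes
# separated by 1 kb gaps, 0-based half-open coordinates.
GENES_PER_CHROM = 1000
GENE_LENGTH = 1000
GENE_GAP = 1000


@dataclass(frozen=True)
class DriverEventSpec:
    """A planted alteration with a transcriptional consequence.

    The altered gene is the TF of ``regulon_index``; its targets are
    shifted by ``effect_size`` biological SDs (sign following each
    target's mode, flipped for deletions).  CNV classes additionally
    apply dosage ``2**log2_ratio`` to the TF gene itself.
    """

    event_class: str
    prevalence: float
    effect_size: float
    regulon_index: int
    log2_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ConfigError(
                f"driver event_class must be one of {EVENT_CLASSES}, "
                f"got {self.event_class!r}"
            )
        if not (0 < self.prevalence < 1):
            raise ConfigError(
                f"driver prevalence must be in (0, 1), got {self.prevalence}"
            )
        if not np.isfinite(self.effect_size) or self.effect_size < 0:
            raise ConfigError(
                f"driver effect_size must be finite and >= 0, got {self.effect_size}"
            )

    def resolved_log2(self) -> float:
        if self.log2_ratio is not None:
            return self.log2_ratio
        return 1.0 if self.event_class == "amplification" else -1.0


@dataclass(frozen=True)
class PassengerEventSpec:
    """A planted alteration with no expression consequence."""

    event_class: str
    prevalence: float

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ConfigError(
                f"passenger event_class must be one of {EVENT_CLASSES}, "
                f"got {self.event_class!r}"
            )
        if not (0 < self.prevalence < 1):
            raise ConfigError(
                f"passenger prevalence must be in (0, 1), got {self.prevalence}"
            )


@dataclass
class CohortSimConfig:
    """Parameters of a simulated cohort.

    ``nb_mean`` sets the scale of the log-normal distribution of per-gene
    baseline means; the means are then rescaled so that their sum equals
    ``library_size``, which is therefore the expected total reads per
    sample.  ``regulon_coupling`` and ``bio_noise_sd`` are the loadings of
    the shared TF factor and the private log-normal noise; their quadrature
    sum is the biological SD in which driver effect sizes are expressed.
    """

    n_samples: int = 400
    n_genes: int = 2000
    n_tfs: int = 10
    targets_per_tf: int = 50
    driver_events: list[DriverEventSpec] = field(default_factory=list)
    passenger_events: list[PassengerEventSpec] = field(default_factory=list)
    nb_mean: float = 50.0
    nb_dispersion: float = 0.2
    library_size: int = 100_000
    regulon_coupling: float = 0.4
    bio_noise_sd: float = 0.3
    positive_mode_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_tfs", "library_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.targets_per_tf < 10:
            raise ConfigError(
                f"targets_per_tf must be >= 10, got {self.targets_per_tf}"
            )
        if self.n_tfs * (1 + self.targets_per_tf) > self.n_genes:
            raise ConfigError(
                "n_genes too small for n_tfs disjoint regulons of "
                f"{self.targets_per_tf} targets"
            )
        if self.nb_mean <= 0:
            raise ConfigError(f"nb_mean must be positive, got {self.nb_mean}")
        if self.nb_dispersion <= 0:
            raise ConfigError(
                f"nb_dispersion must be positive, got {self.nb_dispersion}"
            )
        for ev in list(self.driver_events) + list(self.passenger_events):
            if ev.prevalence * self.n_samples < 1:
                raise ConfigError(
                    f"prevalence {ev.prevalence} yields < 1 expected carrier "
                    f"at n_samples={self.n_samples}"
                )
        for ev in self.driver_events:
            if not (0 <= ev.regulon_index < self.n_tfs):
                raise ConfigError(
                    f"regulon_index {ev.regulon_index} out of range [0, {self.n_tfs})"
                )

    @property
    def bio_sd(self) -> float:
        """Marginal SD of the log-scale biological variation."""
        return float(np.hypot(self.regulon_coupling, self.bio_noise_sd))


@dataclass
class SimulatedCohort:
    """A simulated cohort plus its ground truth."""

    config: CohortSimConfig
    counts: ExpressionMatrix
    mean_counts: pd.DataFrame  # expected counts (NB means), genes x samples
    truth_events: EventMatrix
    regulons: list[Regulon]
    clusters: list[GeneCluster]
    segments: list[CnvSegment]
    gene_models: list[GeneInterval]
    driver_specs: dict[str, DriverEventSpec]


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def make_gene_models(genes: list[str]) -> list[GeneInterval]:
    """Deterministic synthetic genome coordinates for a gene list."""
    models = []
    for i, g in enumerate(genes):
        chrom = f"chr{i // GENES_PER_CHROM + 1}"
        start = (i % GENES_PER_CHROM) * (GENE_LENGTH + GENE_GAP)
        models.append(GeneInterval(g, chrom, start, start + GENE_LENGTH))
    return models


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Draw one cohort: counts, truth events, regulons, clusters, segments."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    width = max(3, len(str(config.n_samples)))
    samples = [f"S{i:0{width}d}" for i in range(config.n_samples)]

    # TFs occupy the front of the gene list; targets are drawn without
    # replacement from the remainder, disjoint across regulons so that the
    # planted coexpression groups are non-overlapping.
    tf_genes = genes[: config.n_tfs]
    pool = rng.permutation(genes[config.n_tfs:])
    regulons: list[Regulon] = []
    modes = np.empty(config.n_genes)
    gene_to_row = {g: i for i, g in enumerate(genes)}
    tf_of_gene = np.full(config.n_genes, -1)
    for ti, tf in enumerate(tf_genes):
        tgt = pool[ti * config.targets_per_tf : (ti + 1) * config.targets_per_tf]
        mode_draw = np.where(
            rng.random(len(tgt)) < config.positive_mode_fraction, 1, -1
        )
        regulons.append(Regulon(tf, dict(zip(tgt, mode_draw.tolist()))))
        for g, m in zip(tgt, mode_draw):
            gi = gene_to_row[g]
            tf_of_gene[gi] = ti
            modes[gi] = m
        # the TF tracks its own factor so its expression carries signal too
        tf_of_gene[gene_to_row[tf]] = ti
        modes[gene_to_row[tf]] = 1

    # baseline means: log-normal around nb_mean, rescaled to library_size
    base = config.nb_mean * rng.lognormal(0.0, 1.0, config.n_genes)
    base *= config.library_size / base.sum()

    # log-scale biological variation: shared TF factor + private noise,
    # equalized so every gene has marginal SD == config.bio_sd
    z = rng.normal(size=(config.n_tfs, config.n_samples))
    eps = rng.normal(size=(config.n_genes, config.n_samples))
    b = np.empty((config.n_genes, config.n_samples))
    in_reg = tf_of_gene >= 0
    b[in_reg] = (
        config.regulon_coupling
        * modes[in_reg, None]
        * z[tf_of_gene[in_reg]]
        + config.bio_noise_sd * eps[in_reg]
    )
    b[~in_reg] = config.bio_sd * eps[~in_reg]

    # Planted events.  Effect sizes are Cohen's-d-like: expressed in units
    # of each target gene's marginal log-expression SD, which includes both
    # the biological variation and the counting noise (delta method:
    # var_log ~ bio_sd^2 + dispersion + 1/mean), so "1 SD" means a shift of
    # one observable standard deviation whatever the gene's depth.
    marginal_log_sd = np.sqrt(
        config.bio_sd**2 + config.nb_dispersion + 1.0 / np.maximum(base, 1e-9)
    )
    truth_rows: dict[str, np.ndarray] = {}
    driver_specs: dict[str, DriverEventSpec] = {}
    dosage = np.ones((config.n_genes, config.n_samples))
    for ev in config.driver_events:
        reg = regulons[ev.regulon_index]
        eid = event_id(reg.tf, ev.event_class)
        carriers = rng.random(config.n_samples) < ev.prevalence
        truth_rows[eid] = carriers.astype(np.int8)
        driver_specs[eid] = ev
        sign = -1.0 if ev.event_class == "deletion" else 1.0
        for g, m in reg.targets.items():
            gi = gene_to_row[g]
            b[gi, carriers] += m * sign * ev.effect_size * marginal_log_sd[gi]
        if ev.event_class in ("amplification", "deletion"):
            dosage[gene_to_row[reg.tf], carriers] *= 2.0 ** ev.resolved_log2()

    # passengers get genes outside every regulon, so their labels are
    # independent of the expression signal by construction
    in_regulon = {g for r in regulons for g in r.targets} | set(tf_genes)
    free_genes = [g for g in genes if g not in in_regulon]
    fi = 0
    for ev in config.passenger_events:
        while f"{free_genes[fi]}:{ev.event_class}" in truth_rows:
            fi += 1
        gene = free_genes[fi]
        fi += 1
        eid = event_id(gene, ev.event_class)
        truth_rows[eid] = (rng.random(config.n_samples) < ev.prevalence).astype(np.int8)

    # negative-binomial draw; exp(b) centered so E[count] == dosage * base
    mu = base[:, None] * np.exp(b - config.bio_sd**2 / 2.0) * dosage
    n_shape = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(n_shape, n_shape / (n_shape + mu))
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)

    if truth_rows:
        truth = EventMatrix(
            pd.DataFrame(truth_rows, index=samples).T.astype(np.int8)
        )
    else:
        truth = EventMatrix(pd.DataFrame(index=pd.Index([]), columns=samples, dtype=np.int8))

    # ground-truth coexpression groups: the positively coupled members of
    # each regulon (negative-mode targets anti-correlate with them)
    clusters = []
    for ti, reg in enumerate(regulons):
        members = [reg.tf] + [g for g, m in reg.targets.items() if m == 1]
        if len(members) >= 10:
            clusters.append(GeneCluster(f"C{ti:02d}", members))

    gene_models = make_gene_models(genes)
    cohort = SimulatedCohort(
        config=config,
        counts=ExpressionMatrix(counts_df, COUNTS),
        mean_counts=pd.DataFrame(mu, index=genes, columns=samples),
        truth_events=truth,
        regulons=regulons,
        clusters=clusters,
        segments=[],
        gene_models=gene_models,
        driver_specs=driver_specs,
    )
    for eid, ev in driver_specs.items():
        if ev.event_class in ("amplification", "deletion"):
            cohort.segments.extend(simulate_cnv_segments(cohort, eid))
    return cohort


def simulate_cnv_segments(cohort: SimulatedCohort, eid: str) -> list[CnvSegment]:
    """SEG records consistent with a planted copy-number event.

    Carrier samples get a segment spanning the altered gene at the event's
    log2 ratio plus neutral flanks covering the rest of the chromosome;
    non-carriers get one neutral chromosome-spanning segment.
    """
    ev = cohort.driver_specs[eid]
    if ev.event_class not in ("amplification", "deletion"):
        raise ConfigError(
            f"event {eid} has class {ev.event_class!r}; "
            "segments exist only for amplification/deletion"
        )
    gene = eid.rpartition(":")[0]
    model = next(m for m in cohort.gene_models if m.gene_id == gene)
    chrom_len = GENES_PER_CHROM * (GENE_LENGTH + GENE_GAP)
    log2 = ev.resolved_log2()
    carriers = cohort.truth_events.values.loc[eid]
    segments = []
    for s in cohort.counts.samples:
        if carriers[s]:
            if model.start > 0:
                segments.append(CnvSegment(s, model.chrom, 0, model.start, 0.0))
            segments.append(CnvSegment(s, model.chrom, model.start, model.end, log2))
            if model.end < chrom_len:
                segments.append(CnvSegment(s, model.chrom, model.end, chrom_len, 0.0))
        else:
            segments.append(CnvSegment(s, model.chrom, 0, chrom_len, 0.0))
    return segments


@dataclass
class SingleCellCohort:
    """Cells derived from a bulk cohort by beta-thinning each sample."""

    cells: ExpressionMatrix  # raw thinned counts, genes x cells
    cell_sample: pd.Series  # cell id -> source sample id
    truth_events: EventMatrix  # events x cells, inherited from source samples


def simulate_single_cell(
    cohort: SimulatedCohort,
    cells_per_sample: int,
    depth: int,
    dropout_shape: float = 0.1,
    seed: int | None = None,
) -> SingleCellCohort:
    """Replicate each sample into cells and thin each to ``depth`` reads.

    Each cell is an independent beta-thinned copy of its source sample's
    count profile; alteration labels are inherited from the source sample.
    Cells whose source total is already <= depth pass through unchanged
    (with a warning from the down-sampler).
    """
    if depth < 1:
        raise ConfigError(f"depth must be >= 1, got {depth}")
    if cells_per_sample < 1:
        raise ConfigError(f"cells_per_sample must be >= 1, got {cells_per_sample}")
    if seed is None:
        seed = cohort.config.seed + 1_000_003
    vals = cohort.counts.values
    rep = pd.DataFrame(
        np.repeat(vals.to_numpy(), cells_per_sample, axis=1),
        index=vals.index,
        columns=[
            f"{s}.c{j}" for s in vals.columns for j in range(cells_per_sample)
        ],
    )
    thinned = downsample_counts(
        ExpressionMatrix(rep, COUNTS),
        DownsampleConfig(f=depth, beta_shape=dropout_shape, seed=seed),
    )
    cell_sample = pd.Series(
        {c: c.rpartition(".c")[0] for c in rep.columns}, name="sample"
    )
    truth_cells = EventMatrix(
        cohort.truth_events.values.loc[:, cell_sample.to_numpy()].set_axis(
            rep.columns, axis=1
        )
    )
    return SingleCellCohort(thinned, cell_sample, truth_cells)
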