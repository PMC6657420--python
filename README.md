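# altexpress

Predict gene-level genomic alterations — somatic mutations,
amplifications, deletions — from gene expression profiles, and measure
how **gene aggregation** makes those predictions robust to noise and
shallow sequencing.

Cancer transcriptomes carry the fingerprints of the genomic events that
shaped them: a driver mutation in a transcription factor, or a dosage
change of an oncogene, reorganizes the expression of the genes it
regulates. `altexpress` turns that observation into per-event binary
classifiers: for each alteration event (e.g. `TP53:mutation`,
`EGFR:amplification`), a gradient-boosted-tree model is trained to
predict carrier status from expression features, evaluated by held-out
AUROC over repeated 75/25 stratified splits. The package is aimed at
computational biologists studying genotype–transcriptome relationships
in bulk cohorts and in single-cell perturbation screens.

Two aggregation strategies collapse genes into fewer, noise-resistant
variables:

* **Regulon activity** — for a TF with signed target set *T* and
  per-gene z-score signature *z*,
  `activity(s) = √|T| · mean_{t∈T} mode(t)·z(t, s)`,
  a unit-variance-calibrated summary of the collective expression change
  of the TF's network;
* **Robust cluster averages** — disjoint coexpression clusters
  (correlation-distance hierarchical clustering, minimum size 10)
  summarized per sample by a one-step Tukey biweight (c = 5).

Two perturbation engines quantify robustness:

* **Gaussian noise** — i.i.d. N(0, σ²) added to the normalized matrix;
* **Beta down-sampling** — each gene's count multiplied by a draw from
  Beta(α, β) with β = 0.1 and α = β·(f/r)/(1 − f/r), where *r* is the
  sample's total reads and *f* the target total; E[thinned total] = f,
  with complete gene dropouts as in shallow single-cell data.

A synthetic-cohort generator (negative-binomial counts, latent-factor
regulons, planted driver/passenger alterations, CNV dosage with SEG
output, single-cell mode with depth-dependent dropout) makes the whole
pipeline testable end to end; see `docs/methods.md` for the model.

## Worked example

```python
from altexpress import (
    CohortSimConfig, DriverEventSpec, simulate_cohort, normalize_counts,
    select_top_variance, build_signature, regulon_activity,
    ModelSpec, repeated_evaluation,
)

cfg = CohortSimConfig(
    n_samples=400, n_genes=2000, n_tfs=10, targets_per_tf=50,
    driver_events=[DriverEventSpec("mutation", prevalence=0.3,
                                   effect_size=1.0, regulon_index=0)],
    seed=7,
)
cohort = simulate_cohort(cfg)                      # counts + planted truth
norm = normalize_counts(cohort.counts)             # median-library log2
labels = cohort.truth_events.values.loc["G0000:mutation"]

expr = select_top_variance(norm, 1000).values      # gene-level features
dist = repeated_evaluation(expr, labels, ModelSpec(seed=1), reps=10)
print(f"expression AUROC {dist.mean:.3f} +/- {dist.sd:.3f}")

act = regulon_activity(build_signature(norm), cohort.regulons)
dist = repeated_evaluation(act, labels, ModelSpec(seed=1), reps=10)
print(f"activity   AUROC {dist.mean:.3f} +/- {dist.sd:.3f}")
```

Output:

```
expression AUROC 0.865 +/- 0.049
activity   AUROC 0.854 +/- 0.051
```

A driver mutation at 30% prevalence that shifts its 50-target regulon by
one (observable) standard deviation is recovered well above chance by
both feature modes; on clean data the two are similar, and the
aggregated features pull ahead once the matrix is perturbed with noise
or down-sampling (see the benchmarks below).

The same stages are exposed on the command line
(`altexpress simulate | events | prep | aggregate | perturb | model |
evaluate | crop-bench`), reading and writing TSV/MTX matrices, SEG
segments, minimal MAF mutations, BED gene models, and regulon/cluster
TSVs.

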