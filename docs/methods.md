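# Methods

`altexpress` implements a framework for predicting the presence of
gene-level genomic alterations — somatic mutations, amplifications, and
deletions — from gene expression profiles, and for measuring how *gene
aggregation* (collapsing genes into regulon activities or robust
coexpression-cluster averages) protects those predictions against noise
and shallow sequencing.

## Event processing

**CNV-to-gene assignment.** A copy-number segment table (SEG; on disk
1-based inclusive start, converted to the package's internal 0-based
half-open convention on read) is mapped to genes by assigning each
(gene, sample) the `log2_ratio` of the segment with the *maximal
base-pair overlap* with the gene interval. Ties are broken by larger
|log2 ratio|, then by leftmost segment start — a deterministic rule that
favors signal; genes no segment touches are neutral (log2 = 0), since
segment files tile the genome in practice and missingness would silently
drop events.

**Binarization.** Amplification is called at log2 ≥ +0.5 and deletion at
log2 ≤ −0.5 (inclusive; roughly one copy gained or lost at a diploid
locus).

**Mutation filtering.** MAF-style variant classes with no
protein-sequence consequence (Silent, UTRs, Intron, IGR, Flanks, RNA)
are discarded, an optional user-supplied gene blacklist is removed, and
the remainder is collapsed to binary gene × sample presence.

**Event filter.** Events are modeled only when carried by 5–95% of
samples *and* by at least 10 samples, all boundaries inclusive. Samples
in which more than 0.5% of genome genes carry any alteration (strict
inequality; a gene counts once across classes) are flagged
"hypermodified" but never removed — the flag is descriptive.

## Normalization and features

Bulk counts: per-sample scaling to the median library size followed by
log2(x + 1). This is a deliberate stand-in for a full model-based
variance-stabilizing transform: any monotone, library-size-corrected log
transform preserves the framework, and the simple form is exactly
reproducible. The pseudocount is 1.0.

Single-cell counts: the standard global-scaling log-normalization
ln(1 + 10,000·count/cell_total); empty cells are dropped with a warning.
Confounders (per-cell molecule counts, cell-cycle scores supplied as
generic numeric covariates) are removed gene-wise by ordinary least
squares; residuals are orthogonal to each covariate by construction.

Feature selection keeps the highest-variance half of the gene set by
default in the benchmarks (1,000 of 2,000 simulated genes, mirroring the
10,000-of-20,531 ratio used on genome-wide data), with deterministic
tie-breaking by gene identifier.

## Aggregation

**Signature.** Each gene is z-scored across samples (population SD,
divisor n; zero-SD genes get zero signature).

**Regulon activity.** For a TF with usable signed targets T (≥ 10
present in the signature), activity in sample s is
`sqrt(|T|) · mean_{t∈T} mode(t)·z(t,s)`. The `sqrt(|T|)` factor gives
the score unit variance under a null of independent unit-variance
target signatures, making activities comparable across regulon sizes.
This signed z-mean is a deliberately simple, fully specified analogue of
rank-based master-regulator activity inference: it reports the
collective expression change of the TF's network relative to each
gene's dataset mean, without likelihood weights or pleiotropy
correction.

**Cluster averages.** Disjoint coexpression clusters come from
average-linkage hierarchical clustering on (1 − Pearson r) distance,
cutting the tree at the height that maximizes the number of clusters of
size ≥ 10 (ties: most genes covered, then lowest height); undersized
clusters are left unaggregated. This replaces a soft-thresholding
topological-overlap pipeline with a simpler method that fulfils the same
role — any disjoint clustering with a minimum size — and cluster
definitions can also be supplied as files. Each cluster × sample cell is
a one-step Tukey biweight: with M the median and S the median absolute
deviation, weights are `(1 − u²)²` for `u = (x − M)/(c·S + eps)` when
|u| < 1 and 0 otherwise (c = 5, eps = 1e-4, the cited implementation's
documented defaults); the estimate is the weighted mean, falling back to
the median if every weight vanishes.

## Perturbation engines

**Gaussian noise** adds i.i.d. N(0, σ²) to every cell of the normalized
matrix; σ is expressed in the same units as the normalized values.

**Beta down-sampling** thins raw counts toward a target total of f reads
per sample. For a sample with total r > f, each gene's count is
multiplied by an independent draw from Beta(α, β) with β = 0.1 and
α = β·(f/r)/(1 − f/r), then rounded half-up. Because E[Beta] = f/r the
expected thinned total is exactly f, while the small β makes the factor
distribution bimodal, producing complete gene dropouts — the signature
of shallow single-cell data. Draws are i.i.d. across genes within a
sample; α is recomputed from each sample's own total. Samples with
r ≤ f pass through unchanged with a warning. Down-sampled matrices are
re-normalized before modeling, since the classifiers consume normalized
features everywhere else.

Perturbation sweeps derive one seed per (level, repetition) from the
base seed via a seed-sequence hash, so every repetition is independent
and the whole sweep reproducible.

## Classification harness

Each event is a binary classification task: features (normalized
expression, activities, or cluster averages) versus carrier status. One
repetition = one stratified 75/25 train/test split (stratification
avoids single-class partitions for events near the 5% prevalence floor;
|train| = round(0.75·n)), a model fit on the training partition, and
AUROC on the held-out quarter. The default algorithm is
histogram-based gradient-boosted trees with the canonical defaults —
100 trees, depth 3, learning rate 0.1, no subsampling; logistic
regression, random forest, k-NN, linear SVM and LDA plug into the same
contract. Hyperparameter grids, when supplied, are resolved by 10-fold
cross-validation on the training partition; with the fixed defaults
nothing is tuned and the model is fit once. Normalization and
feature-variance statistics are computed on the full matrix (matching
the protocol the harness reproduces); repeated evaluation runs
independent splits with a deterministic per-rep seed schedule, and
bootstrap evaluation refits on resamples (with replacement) of the
training samples against a fixed test partition. Degenerate repetitions
are skipped and counted, never imputed. Class imbalance is left as-is:
AUROC is threshold-free.

AUROC is computed by the Mann–Whitney rank formulation (average ranks;
ties earn half credit), which equals the trapezoidal area under the ROC
curve exactly. Paired model comparison uses the two-tailed Wilcoxon
signed-rank test on per-repetition AUROC differences (zero differences
dropped; exact null for ≤ 25 informative pairs, normal approximation
with continuity correction above — the 100-repetition regime).

## Synthetic cohorts

The generator produces cohorts with the statistical structure the
analysis assumes, so every stage is testable without external data.

* **Counts**: negative binomial with dispersion 0.2; per-gene baseline
  means are log-normal (shape set by `nb_mean`) and rescaled so their
  sum equals the target library size (100,000 reads/sample by default
  over 2,000 genes).
* **Coexpression**: each of the TFs drives a disjoint regulon
  (50 signed targets by default, 75% positive mode) through a shared
  per-sample latent factor with loading 0.4 on the log scale, plus
  private log-normal noise of SD 0.3; non-regulon genes receive
  equal-variance private noise, so every gene has marginal biological
  log-SD 0.5.
* **Drivers**: carriers are Bernoulli(prevalence); each target's
  log-mean shifts by `effect_size` × that gene's *marginal*
  log-expression SD (delta-method: `sqrt(bio_sd² + dispersion +
  1/mean)`), i.e. effect sizes are Cohen's d on the observable scale —
  "1 SD" means one observable standard deviation regardless of the
  gene's depth. Deletion-class drivers flip the shift sign; CNV drivers
  additionally multiply the altered gene's (the regulon TF's) expected
  count by 2^log2 and can be rendered as a SEG table with neutral
  flanks.
* **Passengers**: Bernoulli carriers with no expression consequence,
  assigned to genes outside every regulon so their labels are
  independent of the signal by construction.
* **Genome**: one chromosome per 1,000 genes, 1 kb genes with 1 kb
  gaps, 0-based half-open — deterministic and overlap-testable.
* **Single-cell mode** replicates each sample into cells and thins each
  cell with the beta down-sampler to the target depth, inheriting the
  source sample's event labels; depth-dependent dropout follows from
  the thinning itself.

What the generator does *not* emulate: chromosome arms and recurrent
CNV peaks, mutational signatures, tumor purity and subclonality,
overlapping regulons, batch effects, or UMI-specific noise. Passing
benchmarks therefore demonstrate that the pipeline recovers the kinds of
signal it models — coordinated regulon shifts and dosage effects — not
that it matches any particular real cohort.

## Benchmark experiment sizes

The bundled experiments use a 400-sample, 2,000-gene cohort with one
30%-prevalence driver shifting a 50-target regulon by 1 SD and a matched
passenger; 20 repetitions for signal recovery; 50 paired repetitions at
the high-noise level (σ = 2× the mean per-gene SD of the normalized
matrix) and 20 at σ = 0; and 8 re-drawn repetitions per depth over
f = r/3, r/5, r/8, r/12 for down-sampling. The down-sampling experiment
uses 5 TFs × 200 targets: aggregation's averaging benefit grows with
regulon size, and a few hundred targets is the size regime of inferred
TF regulons; with 50-target regulons both feature modes degrade
together and no clean crossover depth exists. These sizes keep each
experiment in the minutes range on one core while leaving the measured
contrasts far from their decision boundaries.

## Known limitations

* The activity score is a linear z-mean; strongly rank-nonlinear target
  responses would favor the rank-enrichment formulation it stands in
  for.
* The clustering cut criterion is greedy over tree heights and can
  split a large homogeneous block into two qualifying clusters when
  within-block correlation is graded rather than uniform.
* The down-sampler's round-half-up can inflate a sample's total by at
  most half a count per gene relative to the continuous expectation.
* Normalization statistics computed on the full matrix leak marginal
  information between train and test; this mirrors the reproduced
  protocol, and the harness carries the hooks to compute them on train
  only.
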