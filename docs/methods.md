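# Methods

## The synthetic cohort model

The generator produces the data-generating structure the analysis assumes,
with every corruption recorded so tests can check that the pipeline undoes
what was done.

**Latent abundances.** Metabolite f in subject i has
log₂ x_if = μ_f + b_if, with μ_f ~ Uniform(10, 20) (a ~1000-fold abundance
dynamic range, typical of MS intensity tables) and biological variation
b_if ~ N(0, 0.6²) in log₂ units. Log-normal baselines keep intensities
positive and right-skewed, which is what makes total-signal (MSTUS)
normalization meaningful.

**Planted effects.** A planted effect shifts one metabolite by
`direction × base_log2_effect × stage_multiplier(stage)` in the groups of
its contrast (pan-cancer, LC vs the gastrointestinal cancers, GC vs CRC,
or any explicit group set). Default stage multipliers are
{I: 0.3, II: 1.0, III: 1.0, IV: 0.6, unknown: 0.8}: effects are muted at
stage I, full at II/III, and partially reverted at IV, so a calibrated
screening model shows the early- and late-stage sensitivity dip that
staged cancer metabolomics cohorts exhibit; "unknown" (non-metastatic,
unstaged) sits between. All values are configurable per effect.

**Corruption.** Each subject sample is multiplied by one dilution factor
exp(N(0, 0.5²)) applied to all features on all platforms — urine
concentration is a whole-sample property, and 0.5 on the natural-log scale
spans roughly a 7-fold typical dilution range. Batch effects are
per-(platform, feature, batch) factors exp(N(0, 0.3²)) shared by subject
and QC rows; measurement noise is per-cell exp(N(0, 0.2²)). QC rows are
replicates of a single fixed reference profile (the cohort's geometric-mean
spectrum) carrying batch effect and noise but no dilution; a shared
reference across batches is precisely what makes QC-anchored correction
identifiable. Cells are censored with probability ramping linearly from 0
at the platform's 15th log-intensity percentile to 0.35 at the minimum,
plus 2% missing-completely-at-random — low-intensity censoring is why
half-minimum imputation exists.

**Design defaults.** Group sizes default to 548 LC / 177 GC / 186 CRC /
563 NCD / 229 HC with a 77/23 stratified discovery/validation split and a
stage mix of 30/11/17/15/27% (I/II/III/IV/unknown); platform sizes default
to 125 polar, 13 lipid and 222 GC metabolites. Batch layout (4 batches,
3 QC injections per batch) is not something the assay design pins down;
the defaults are arbitrary and exposed in the config. Ages are drawn so
the cancer arm is oldest (median ≈ 62) and healthy controls youngest
(≈ 47): age is deliberately confounded with group, while metabolite levels
are age-independent.

## Preprocessing

Order is fixed: detection filter → batchwise imputation → MSTUS →
QC-median batch correction → log₂ + scaling.

- **Detection filter:** features observed in < 80% of subject samples are
  dropped (QC rows excluded from the denominator; exactly 80% is kept).
- **Imputation** runs per batch, subject and QC rows separately. A feature
  with batch missing rate ≤ 0.3 *and* mean observed intensity above the
  batch's 25th percentile is imputed by scikit-learn's iterative
  chained-model imputer on log scale (5 rounds, ≤ 20 predictor features);
  anything else with missing cells gets half its minimum observed value in
  the batch; a feature entirely missing in a batch gets half its global
  minimum, with a warning. The two numeric routing thresholds are not
  dictated by the underlying idea ("low missing rate and high average
  intensity") and are exposed in `PreprocessConfig`. Observed cells are
  never altered.
- **MSTUS:** each sample is divided by its summed intensity over the
  "useful" set — features observed pre-imputation in 100% of subject
  samples (falling back to all retained features if that set is empty).
  Division by a per-sample total cancels the dilution factor exactly; the
  operation is invariant to any per-sample rescaling of the input. MSTUS
  runs per platform because platforms are acquired separately. Note the
  assumption this inherits: disease effects must be a small share of total
  signal. If a highly abundant metabolite carries a large fold change, the
  denominator itself shifts with the class and every feature's contrast is
  attenuated — visible in the generator when a marker is planted on a
  dominant feature.
- **QC-median batch correction:** in log space, each (feature, batch) is
  shifted so the batch's QC median equals the grand QC median; subject and
  QC rows get the same shift. This is a deliberate, simple stand-in for
  representation-learning batch correctors: the contract — QC-anchored
  removal of additive-in-log batch effects — is the same, it is exactly
  identifiable under the generator's batch model, and it is testable (the
  pooled-QC relative SD must drop). The mode flag allows plug-ins.
- **Scaling:** log₂, then per-feature centering/scaling (unit-variance by
  default, pareto available). Parameters are fitted on discovery subject
  samples only and reapplied to validation — the alternative (global
  fitting) leaks validation information into the transform.

## Panel selection

Ensemble LASSO in the stability-selection style: `n_rounds` (default 100)
stratified subsamples of 80% of the discovery samples; on each, an
L1-penalized logistic regression (all endpoints here are binary
classifications, so the linear-model penalty is applied to a logistic
likelihood) with the penalty chosen per round by stratified 3-fold CV over
a fixed C grid. The default rule is conservative ("cv-1se"): the strongest
penalty whose mean CV AUC is within one across-fold SD of the best. That
choice is what makes frequency voting discriminative — with the
CV-optimal penalty at these sample sizes, weak null features are retained
stably and panel precision collapses; with the sparse rule, null features
fall below the 0.8 frequency threshold and permuted-label runs return
empty panels. Class imbalance is handled by class-weighted loss
(matching the balanced SVM downstream); ties in frequency break by mean
|coefficient|, then feature ID, so selection is deterministic and
invariant to column order. Panel size is data-dependent; a `target_size`
mode picks the top-k by frequency when a fixed-size panel is wanted.

## Screening and calibration

The scorer is a class-weight-balanced SVM (linear kernel by default — the
panels are small, and linear decision scores keep threshold calibration
stable; rbf is in the grid) tuned by 5-fold stratified CV repeated 5
times, maximizing mean AUC, then refitted on the full discovery set. Raw
decision scores are used for ROC and thresholding; Platt calibration is
only fitted where probabilities are actually multiplied (the origin
hierarchy).

The operating threshold is set on discovery control scores only: the
smallest value such that at most ⌊(1−s)·n⌋ of n controls score at or above
it, ties stepping past the tied score. This guarantees achieved
specificity ≥ target on the calibration data and makes "specificity
> 99 %" an explicit construction. Statistically, the threshold sits just
past the (n−k)th order statistic of the control scores, so its true
specificity is Beta(n−k, k+1) distributed; on m fresh controls the number
scoring below threshold is Beta-Binomial(m, n−k, k+1). The test suite
checks calibration against that exact compound band — a plain binomial
band around the target ignores the calibration-sample noise and would
reject a correctly calibrated threshold in a large fraction of runs.

Stage-stratified detection rates (sensitivity at the fixed threshold) come
with exact Clopper-Pearson 95% intervals; empty strata are reported as
undefined, not zero. The age check is a plain Pearson correlation between
scores and ages with a two-sided p-value.

## Tumor origin

Stage 1 scores LC vs non-LC on panel A; stage 2 scores GC vs CRC on panel
B, selected with panel A excluded so disjointness holds by construction
(and is asserted at model assembly). Both stages are balanced SVMs with
sigmoid (Platt) probability calibration fitted by internal CV, because the
hierarchy multiplies probabilities: P(LC), (1−P(LC))·P(GC|non-LC),
(1−P(LC))·(1−P(GC|non-LC)) — an exact simplex point per sample. The
hierarchical mode is the default because its probability bookkeeping is
exact; an "ovr-stacked" mode (25-replicate bagged one-vs-rest scorers on
the pooled panel plus a regularized logistic stacker over the five base
scores, trained on out-of-fold stage-1 probabilities) implements the
ensemble alternative and is benchmarked against it in the tests. Predicted
label is the first maximum in class order, i.e. ties resolve
LC > GC > CRC.

## Evaluation and enrichment

AUC is the Mann-Whitney concordance probability with ties counted 1/2
(checked against a brute-force pairwise oracle); the ROC convention is
score ≥ threshold ⇒ positive. Confidence intervals default to the
stratified percentile bootstrap (2000 replicates, positives and negatives
resampled separately; seeded, hence deterministic), with DeLong as a
closed-form alternative.

Enrichment is the one-sided hypergeometric upper tail P(X ≥ k) per
pathway over the annotated background (default: all annotated metabolites
of the input tables), with Benjamini-Hochberg q-values reported alongside;
the significance flag follows the raw p < 0.05 convention, with q-values
available for stricter readings. The bundled pathway map is synthetic: 15
KEGG-style pathways over ~70 of the generator's metabolite IDs, built so
that the demo's planted markers fall coherently into named pathways
(tryptophan, starch/sucrose, histidine, glutathione, fructose/mannose,
arginine/proline metabolism, …). It carries no real biochemistry and
exists so enrichment is exercisable offline.

## Reproducibility

One global seed drives everything: per-module seeds derive from it by a
fixed keyed scheme (`derive_seed(seed, module_name)`, a multiplicative
hash plus CRC32 of the name, reduced below 2³¹), per-round selection seeds
spawn from the module seed keyed by round index (not by column position),
and all JSON output is written with sorted keys and fixed float rounding.
Two runs with the same config and seed produce byte-identical metric
files; the test suite asserts this.

## Problem sizes used in tests and the acceptance script

The bundled experiments run at reduced scale, chosen as the package's own
working sizes: cohorts of 150-900 subjects, 45-100 features over one or
two platforms, 40-50 selection rounds, 200-500 bootstrap replicates. The
defaults in the library itself (Table-1-scale group sizes, 360 features,
100 rounds, 2000 bootstrap replicates) remain the study-scale
configuration.

## Known limitations

- The generator's effects are additive in log scale, independent across
  markers, and identically scaled within a contrast; real metabolite
  co-regulation, correlated marker blocks and LC/GC/CRC-shared partial
  effects are not modeled. Passing recovery tests therefore demonstrate
  correctness of the machinery, not expected performance on real cohorts.
- Metabolite levels are age- and sex-independent by construction, while
  age differs by group; the age-confounding check on synthetic data
  consequently reflects group separation, not a metabolite-age link.
- Batch effects are additive in log and fully shared between subject and
  QC samples; drift within a batch (injection order) is not simulated, so
  the QC-median corrector is exactly matched to the generator. On real
  data a QC-anchored smoother or autoencoder-based corrector may be
  needed; the `batch_correction_mode` flag is the plug-in point.
- Raw spectra processing (peak picking, alignment, annotation) and assay
  chemistry are out of scope; the pipeline starts from annotated intensity
  tables.
- The bundled pathway map is synthetic; enrichment on real panels needs a
  real metabolite→pathway annotation in the same two-column TSV format.
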