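# urometab

Urinary-metabolomics multi-cancer screening and tumor-origin prediction,
as a tested, reproducible pipeline.

Urine is an attractive medium for multi-cancer early detection (MCED):
collection is non-invasive, sample volume is essentially unlimited, and the
urinary metabolome reflects systemic metabolic reprogramming across tumor
types. This package implements the full analysis such a study needs, from
raw per-platform metabolite intensity tables to calibrated screening
decisions and a tissue-of-origin call:

1. **Synthetic cohort generation** (`urometab.cohort`) — three MS platforms
   (polar / lipid / GC; 125, 13 and 222 metabolites by default), five
   clinical groups (lung, gastric and colorectal cancer; benign-disease and
   healthy controls), per-sample urine dilution, per-batch instrument
   effects with pooled QC injections, log-normal noise, censoring-at-low-
   intensity plus random missingness, and stage-dependent planted group
   effects with a recorded ground truth. The study's raw data are not
   public, so every downstream stage is developed and tested against this
   generator.
2. **Preprocessing** (`urometab.preprocess`) — detection filter (features
   seen in < 80% of subject samples are dropped), batchwise conditional
   imputation (iterative chained-model imputation for low-missingness /
   high-intensity features, half-minimum for the rest), MSTUS total-useful-
   signal normalization, QC-median batch correction in log space, and
   log₂ + autoscaling fitted on the discovery cohort only.
3. **Panel selection** (`urometab.panels`) — stability-style ensemble LASSO:
   repeated stratified subsampling, L1-penalized logistic fits with an
   internally cross-validated penalty, frequency voting, per-platform
   selection with merging, and exclusion sets for building disjoint panels.
4. **Screening** (`urometab.screening`) — class-weight-balanced SVM tuned by
   5×5 repeated stratified CV, with decision thresholds anchored to a target
   specificity (e.g. > 99% for population screening, 95% for high-risk
   groups) on discovery controls, stage-stratified detection rates with
   exact binomial CIs, and a score-vs-age confounding check.
5. **Tumor origin** (`urometab.origin`) — two-stage model: LC vs non-LC on
   panel A, GC vs CRC on a disjoint panel B, composed hierarchically into
   exact three-class probabilities P(LC), (1−P(LC))·P(GC|non-LC),
   (1−P(LC))·(1−P(GC|non-LC)); an optional bagged one-vs-rest + stacking
   mode is included.
6. **Evaluation & enrichment** (`urometab.evaluation`, `urometab.enrichment`)
   — Mann-Whitney AUC with stratified bootstrap (or DeLong) CIs, confusion
   matrices, and hypergeometric pathway over-representation with BH
   q-values against a bundled synthetic KEGG-style pathway map.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (seed 2024; 80 LC / 50 GC / 50 CRC / 60 NCD / 60 HC subjects, 360
features, planted pan-cancer, LC-specific and GC-specific marker sets):

```bash
cd analysis
python 01_simulate_cohort.py
python 02_preprocess.py
python 03_select_panel.py
python 04_screening_performance.py
python 05_tumor_origin.py
python 06_pathway_enrichment.py
```

`03_select_panel.py` recovers a 12-metabolite screening panel (the nine
planted pan-cancer/LC markers at frequency 1.0 plus three near-threshold
entries), and `04_screening_performance.py` prints, for that seed:

```
validation AUC (cancer_vs_hc): 0.925 (95% CI 0.847-0.983)
validation AUC (cancer_vs_noncancer): 0.936 (95% CI 0.875-0.984)
detection at 95% specificity by stage: I:45% II:100% III:100% IV:100%
detection at 99% specificity by stage: I:45% II:100% III:100% IV:67%
score-age correlation: R = 0.15, P = 0.2
```

Reading: the panel separates validation cancers from controls well (the
demo cohort is small, hence the wide bootstrap intervals); detection dips
at stage I, where the generator mutes planted effects, and at stage IV at
the stricter 99% operating point, where they are partially reverted —
the early/late sensitivity dip the stage-dependent effect model encodes.
The score-age correlation is mild and non-significant here even though
the generator makes cancer patients older, because metabolite levels
themselves are age-independent. `05_tumor_origin.py` reports two disjoint
panels (6 + 3 metabolites containing the planted LC- and GC-specific
marker sets) and perfect three-class separation at this demo effect size,
and `06_pathway_enrichment.py` flags tryptophan metabolism (k=3/5,
p=0.025), the pathway the planted polar markers belong to in the bundled
synthetic map.

Equivalently, one call chains everything and writes a machine-readable
summary:

```python
from urometab import RunConfig, run_pipeline
metrics = run_pipeline(RunConfig(seed=1), outdir="out/")
```

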