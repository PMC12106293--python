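# amspipe

Multi-omics biomarker discovery and acute-mountain-sickness (AMS) prediction
pipeline: plasma protein and metabolite abundance matrices plus a clinical
table go through quality control, protein–metabolite co-expression module
discovery, mutual-information-driven recursive feature elimination, and a
radial-kernel SVM prediction model with SHAP attributions and decision-curve
analysis. Because no real cohort ships with the package, a synthetic-cohort
generator with a ground-truth manifest drives every stage and the test suite.

## Stages

1. **Synthetic cohort** (`amspipe.cohort`) — latent-factor block model:
   features load on module factors, AMS-associated modules shift with the
   ordinal illness degree, a small set of informative features carries an
   additional standardized effect; clinical variables follow configurable
   group medians (systolic blood pressure up, peak expiratory flow down in
   AMS). MCAR missingness, >5-SD outlier cells, and globally shifted samples
   can be injected on top; everything is recorded in `truth.json`.
2. **QC** (`amspipe.preprocess`) — per-sample outlier masking (>5 SD),
   sample exclusion by missingness (>20%, proteins only) and by
   Kolmogorov–Smirnov distance against the pooled distribution
   (fence = Q3 + 1.5·IQR), feature exclusion by missingness (>50% proteins,
   >10% metabolites), log2 transform, predictive-mean-matching imputation
   (chained equations), and full-pairwise cyclic loess normalization.
3. **Module discovery** (`amspipe.modules`) — concatenated omics,
   1 − Spearman dissimilarity, Ward clustering (ward.D2), dynamic hybrid
   tree cut (minClusterSize 45), eigengene computation, merging of close
   modules (cutHeight 0.4), and Pearson module–trait association with BH
   correction; modules significant against the AMS degree form the
   molecular feature pool.
4. **Feature selection** (`amspipe.selection`) — Mann–Whitney / Fisher
   clinical screen, MI-radialSVM-RFE (3-fold, halve.above 100), CV error
   curve over the top 1..30 features, and a univariate-logistic filter with
   Bonferroni correction.
5. **Prediction model** (`amspipe.model`) — radial SVM with Platt-calibrated
   probabilities, ROC/AUC, accuracy, calibration curve, exact kernel SHAP
   (full coalition enumeration), decision-curve analysis, and per-phenotype
   (clinical / protein / metabolite) sub-models.

## CLI

```bash
amspipe run --simulate --seed 7 --out results/run7      # full pipeline
amspipe simulate --seed 7 --out cohort/                 # just the cohort
amspipe qc cohort/proteins.tsv --omic protein --out qc
amspipe discover-modules qc_protein.tsv qc_metabolite.tsv cohort/clinical.tsv
amspipe select-features features.tsv cohort/clinical.tsv --seed 7
amspipe train panel.tsv cohort/clinical.tsv --out model.json
amspipe evaluate model.json panel.tsv cohort/clinical.tsv
```

`amspipe run` accepts `--config config.yaml` overriding any default
(thresholds, module parameters, SVM settings, seeds) and writes all stage
artifacts — TSV tables, `model.json`, `evaluation.json`, SVG plots, and a
`run_manifest.json` with per-file checksums; identical config + seed
reproduces identical checksums.

## Layout

```
src/amspipe/
  cohort.py      synthetic cohort generator + ground-truth manifest
  matrix.py      AbundanceMatrix / clinical table TSV formats
  preprocess.py  QC chain (masking, filters, PMM, cyclic loess)
  modules.py     co-expression modules, eigengenes, module-trait tests
  selection.py   clinical screen, MI estimator, MI-SVM-RFE, logistic filter
  model.py       radial SVM, ROC, calibration, kernel SHAP, DCA
  pipeline.py    orchestration, config, run manifest
  cli.py         click CLI (simulate / qc / discover-modules / ...)
```
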