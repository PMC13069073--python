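# stratomic

Consensus machine-learning stratification of clinical–proteomic cohorts.

`stratomic` implements, end to end, an integrated analysis of label-free
quantitative (LFQ) serum proteomics plus routine clinical chemistry for
three-group case/control stratification (healthy controls `CTRL`,
dyslipidemic `DLP`, advanced-atherosclerosis `AT`):

* **`synthetic`** — seeded synthetic cohort generator: log-normal protein
  intensities with correlated clusters and group effects,
  intensity-dependent (MNAR) plus uniform (MCAR) missingness, clinical
  features with group-shifted means. Ships presets (`paper_discovery`,
  `paper_external`, `split_signal`, `smoke`).
* **`proteomics`** — LFQ post-processing: log2 transform → ≥70%
  valid-value filter → per-sample downshifted-normal imputation →
  quantile normalization → two-sample t-test with permutation-estimated
  FDR (q-values).
* **`clinical`** — kNN imputation (k=5, inverse-distance-weighted partial
  Euclidean) and leakage-safe train-only standardization.
* **`selection`** — consensus feature selection: repeated stratified CV,
  stratified bootstraps inside each training fold, RFE (coefficients /
  impurity importances) or univariate-F fallback per model family,
  ≥3-of-5 selector votes per bootstrap, ≥60% bootstrap retention per fold,
  ≥20% fold-level consensus, and |Spearman ρ| ≥ 0.85 cluster dedup.
* **`bench`** — five classifier families (NB, LSVM, RF, ETC, AB) behind a
  uniform probabilistic interface; repeated stratified CV metrics with 95%
  percentile intervals; add-one permutation significance tests; consensus
  feature-importance rankings.
* **`stats`** — binary ROC/AUC with Youden cutoffs, the dual-comparison
  AUC > 0.7 biomarker filter, |Spearman R| > 0.6 correlation screens,
  Kruskal–Wallis/Dunn and chi-square baseline tests.
* **`stratify`** — per-individual, per-model out-of-fold misclassification
  probabilities; consensus reassignment when ≥3 of 5 models exceed 50%;
  per-modality misclassification rates and cross-modality comparison.
* **`pipeline` / `cli`** — config-driven orchestration over three
  modalities (clinical-only, proteomic-only, combined) with a manifest
  that reproduces every output byte-for-byte.

## Quick start

```sh
# generate a synthetic discovery cohort (TSV/CSV, plain text)
stratomic simulate --preset paper_discovery --out cohort/

# full pipeline on a preset (or --config run.yaml for file-based input)
stratomic run-all --preset smoke --out run/ --seed 1

# individual stages
stratomic prep --proteins cohort/proteins.tsv --labels cohort/labels.csv --out prep/
stratomic validate --proteins cohort/proteins.tsv --clinical cohort/clinical.csv --labels cohort/labels.csv
```

A run directory contains `differential.csv`, `feature_panel.csv`,
`metrics.csv`, `roc_results.csv`, `misclass_matrix.csv`,
`stratification.csv`, `modality_comparison.csv`, a `manifest.json` (rerun
with identical bytes via `stratomic.pipeline.run_from_manifest`), and a
human-readable `summary.txt`.

## Tests

```sh
python -m pytest -q
```

The suite includes per-module unit tests, property tests of the documented
invariants, and `tests/test_acceptance.py`, which checks the acceptance
criteria (permutation-null calibration, oracle equivalences, FDR null
calibration, marker recovery on the `paper_discovery` preset, consensus-rule
logic, modality-integration direction, and byte-level reproducibility).

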