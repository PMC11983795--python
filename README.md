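# epiperf

Stratified performance evaluation of DNA-methylation-based phenotype
predictors (epigenetic clocks, a telomere-length estimator, plasma-protein
surrogates, and cell-proportion estimates), with:

- **`epiperf.synthetic_data`** — a cohort simulator with exactly known truth:
  five race/ethnicity groups with fixed sizes, configurable per-group
  correlation and bias between each laboratory measure and its DNAm
  prediction, log-normal lab distributions, and exact-count injection of
  top-coded ages, sex-prediction mismatches, extreme log-scale outliers, and
  per-measure missingness (all on disjoint rows, so the QC audit recovers
  every configured count to the row).
- **`epiperf.qc_conversions`** — exclusion rules (sex-prediction mismatch,
  top-coded ages for age predictors, per-measure missingness, inclusive
  >= 3-SD log-scale outliers on laboratory values), unit conversions
  (telomere T/S ratio to kilobase pairs, exponentiation of log-scale
  CRP/HbA1c predictions, B + CD4 + CD8 lymphocyte aggregation), and a full
  removal audit per analysis.
- **`epiperf.performance_metrics`** — Pearson correlation and median
  absolute error, overall and stratified by race/ethnicity or sex, with the
  historical 0.35 correlation threshold flag for protein predictors.
- **`epiperf.bootstrap_inference`** — percentile-bootstrap inference on
  between-group differences in correlation and MAE (participants resampled
  jointly within groups; median difference with 2.5th/97.5th percentile CI;
  significance = CI excludes 0), including the equal-n sensitivity variant
  that caps every group at the smallest group's size.
- **`epiperf.regression_models`** — interaction OLS models (prediction ~
  phenotype x group + covariates) at two adjustment levels, with fixed
  Bonferroni budgets (150 minimal / 120 full) and a two-tier
  significant/suggestive classification.
- **`epiperf.reporting`** — end-to-end pipeline orchestration with a
  checksummed, byte-reproducible result bundle, plus heatmap / difference
  grid / forest-plot rendering.

## Command line

```sh
epiperf simulate --config sim.yaml --out sim/            # synthetic cohort + truth table
epiperf qc --in sim/population.tsv --out qc/             # removal audit
epiperf metrics --in sim/population.tsv --by race_ethnicity,sex --out metrics.tsv
epiperf bootstrap --in sim/population.tsv --iters 10000 --variant standard --seed 1 --out boot.tsv
epiperf regress --in sim/population.tsv --modifier race_ethnicity --adjustment minimal --out reg.tsv
epiperf run --config study.yaml --out results/ --figures # full pipeline
```

All tables are tidy tab-delimited text; missing values are empty fields.
Configuration files are YAML and round-trip losslessly
(`epiperf.SimulationConfig` / `epiperf.StudyConfig`).

## Python API sketch

```python
import epiperf as ep

cfg = ep.SimulationConfig(seed=1)           # survey-like defaults: 2,472 rows
table = ep.simulate_population(cfg)
truth = ep.truth_table(cfg)                 # generating (rho, bias) per predictor x group

clean, audit = ep.apply_global_qc(table)    # sex-mismatch removal
aset = ep.build_analysis_set(clean, ep.DEFAULT_SPECS[1])   # hannum
metrics = ep.stratified_metrics(aset, "race_ethnicity")
comp = ep.bootstrap_group_difference(...)   # or ep.all_pairwise_comparisons(...)
fit = ep.fit_interaction_model(aset, "race_ethnicity", "minimal")
```

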