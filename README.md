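# pcufe

Principal-component based unsupervised feature extraction for two-class
biomarker discovery in feature-by-sample expression matrices (e.g.
miRNA microarray intensities), with a synthetic cohort generator that
makes every stage verifiable without external data.

## Method

Given a feature-by-sample matrix `x_ij` (N features, M samples) and a
two-level class label per sample:

1. **Per-sample normalization** — each sample column is centered and
   scaled across features so that `sum_i x_ij = 0` and `sum_i x_ij^2 = N`
   (population denominator; optional `log2(x + pseudocount)` first).
2. **PCA** — scores `u_li` (unit-norm eigenvectors of the feature Gram
   matrix, via thin SVD) and loadings `v_lj = sum_i x_ij u_li`.
3. **Component selection** — each component's loading vector is tested
   for a class-location difference (two-group F-test, equivalent to the
   squared two-sample t); Benjamini–Hochberg across components; keep
   adjusted p < 0.05 (or supply an explicit component set).
4. **Feature scoring** — `T_i = sum_{l in Omega} (u_li / sigma_l)^2` with
   `sigma_l` the dispersion of the score entries; upper-tail chi-squared
   p-value with `|Omega|` degrees of freedom; BH across features; keep
   adjusted p < 0.01.
5. **Stage-2 recomputation** — PCA and loadings recomputed on the
   selected-feature submatrix (not re-normalized by default;
   `--renormalize-stage2` for the alternative); component set re-chosen
   or overridden.
6. **Discrimination** — two-class Fisher LDA on the recomputed loadings;
   confusion matrix, ROC and trapezoidal AUC, either in-sample or with
   leave-one-out cross-validation (feature selection inside each fold).

Component indices are 1-based everywhere user-facing; strict `<` is used
at both thresholds.

## CLI

```sh
pcufe simulate --preset v20_hcv_svr --seed 17 --out cohort/
pcufe normalize --in cohort/matrix.tsv --out norm.tsv --log2
pcufe run --matrix cohort/matrix.tsv --annot cohort/annotation.csv \
    --log2 --alpha-components 0.05 --alpha-features 0.01 --out results/
pcufe evaluate --mode loocv --matrix cohort/matrix.tsv \
    --annot cohort/annotation.csv --log2 --out results/
pcufe all --effect-size 2.0 --seed 1 --out full_run/
```

`run`/`evaluate` also accept `--omega1`/`--omega2` (comma-separated
1-based component overrides) and `--config config.yaml` mirroring all
flags. Outputs: `features.tsv` (statistic, raw/adjusted p, selected
flag), `components.tsv` (eigenvalue, association p, membership),
`roc.tsv`, and `summary.json` (config echo, seed, omegas, confusion
matrix, AUC). Identical config + seed reproduce byte-identical files.

## File formats

* **Expression TSV** — header `feature_id<TAB>sample1<TAB>...`, one
  feature per row, values numeric or a missing token (default `NA`;
  features with any missing value are dropped and counted in the log).
  Numbers are serialized with 12 significant digits.
* **Annotation** — two columns `sample_id,class_label` (comma or tab),
  exactly two distinct labels, ≥ 2 samples each. Class index 1 is the
  lexicographically smaller label; class 2 is the ROC-positive class.

GEO series-matrix files are not parsed directly; convert one externally
with e.g. `awk`/pandas into the TSV dialect above.

## Library use

```python
from pcufe import (CohortParams, UFEConfig, generate_two_class_cohort,
                   log_transform, normalize_samples, run_ufe,
                   evaluate_in_sample, loocv_evaluate)

cohort = generate_two_class_cohort(CohortParams(effect_size=2.0, seed=1))
matrix = normalize_samples(log_transform(cohort.matrix))
result = run_ufe(matrix, cohort.annot, UFEConfig())
disc, _ = evaluate_in_sample(matrix, cohort.annot, ufe_result=result)
print(result.omega1, result.selected_features, disc.auc)
```
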