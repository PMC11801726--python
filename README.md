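# methylpredict

Train and evaluate DNA-methylation-derived predictors of phenotypic traits
(chronological age, environmental exposures) from a beta matrix, using three
training strategies side by side:

1. **CpG predictor** — cross-validated elastic net directly on probe betas;
   the classic sparse "clock" (a linear combination of a few probes).
2. **PCA predictor** — PCA of the training beta matrix, low-variance
   component trimming, then a cross-validated elastic net on the principal
   component scores; new samples are projected with the *training* centering.
3. **SL PCA predictor** — a SuperLearner-style stacked ensemble on the full
   PC score matrix: a library of candidate learners (elastic nets across a
   mixing-parameter ladder, a mean-only learner, optionally a smooth
   additive learner) is cross-validated on shared folds and combined with
   non-negative, sum-to-one weights minimizing cross-validated squared error.

The package also ships the evaluation machinery — Pearson correlation,
**median** absolute error, paired bootstrap comparison of two predictors,
replicate-pair agreement, and epigenetic age acceleration (EAA) residual
analyses — plus a seeded synthetic-study generator so the entire pipeline is
testable offline with known ground truth.

## Data formats

* **Beta matrix**: delimited text (TSV/CSV), probes as rows, first column
  probe IDs, header row sample IDs (the series-matrix convention). Values in
  [0, 1]; non-numeric cells are treated as missing and imputed with training
  probe means. A flag flips the orientation.
* **Phenotypes**: CSV with a header; column roles (sample ID, target,
  covariates, cell proportions, replicate group) are specified in the config.
* **Models**: a directory with `manifest.json` plus flat delimited numeric
  arrays (`center.tsv`, `rotation.tsv`, `coefficients.tsv`) — fully
  plain-text and portable; a save/load round trip reproduces predictions
  bit-for-bit.

## CLI

```bash
# simulate a synthetic study (beta TSV + phenotype CSV + truth JSON)
methylpredict simulate --config sim.yaml --out-prefix study

# train one predictor, or all three (PCA is run once and shared)
methylpredict train --method all --beta study.beta.tsv \
    --pheno study.pheno.csv --config train.yaml --out models/

# predict with a saved model
methylpredict predict --model models/slpca --beta study.beta.tsv --out pred.csv

# evaluate fit (and replicate-pair agreement)
methylpredict evaluate --model models/pca --beta study.beta.tsv \
    --pheno study.pheno.csv --replicates

# paired bootstrap comparison of two predictors
methylpredict compare --models models/cpg,models/pca --beta study.beta.tsv \
    --pheno study.pheno.csv --bootstrap 10000 --seed 1

# seeded train/test split permutations
methylpredict split --n 673 --test-fraction 0.25 --permutations 10 --seed 1
```

Training config keys (YAML): `alpha` (elastic-net mixing, default 0.5),
`n_folds` (10), `seed`, `age_transform` (`identity` | `log_child`),
`adult_age_knot` (21), `trim_count` (`auto` | int), `library`
(`age` | `complex_trait`), `n_lambda`, `lambda_min_ratio`,
`max_missing_frac`, `target_col`, `sample_id_col`, `cell_cols`,
`replicate_col`, `exclude_outliers`, `outlier_mad_k`.

Exit codes: 2 = I/O error, 3 = validation error, 4 = numerical error.

## Age transforms

Child ages can be trained on the transformed scale
`log(age + 1) − log(knot + 1)` (knot 21 years); gestational ages convert to
years via `−((39 − GA)/52.1429)` so a 39-week birth is age 0. Predictions
are always inverted back to years before metrics are computed.

## Python API sketch

```python
import methylpredict as mp

cfg = mp.SyntheticConfig(n_samples=200, n_probes=2000, n_signal_probes=20, seed=1)
beta, pheno, truth = mp.generate_study(cfg)

models = mp.train_all(beta, pheno, mp.PipelineConfig(seed=1))
pred = mp.predict_pca(models["pca"], beta)
report = mp.evaluate_predictions(pred, pheno.target, method="pca")

mp.save_model(models["slpca"], "models/slpca")
```
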