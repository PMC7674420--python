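# wlpred

Weight-loss responder classification from baseline multi-omics data, as a
tested, reusable pipeline. `wlpred` classifies observations from crossover
dietary-intervention trials as weight-loss responders (any relative weight
decrease) or non-responders (no change or gain) using random-forest models
over heterogeneous baseline feature blocks — diet arm, clinical variables,
16S and shotgun gut-microbiome abundances, urine metabolites, SNP dosages
and genetic risk scores, and postprandial time-series volatility features.
A synthetic-cohort generator with planted effects and block-wise
missingness makes the whole analysis runnable and testable without any
external data.

## Components

| Module | Role |
| --- | --- |
| `wlpred.synthetic` | Crossover cohorts with planted predictive effects, LD-structured genotypes, postprandial series, block-wise missingness |
| `wlpred.labels` | Relative weight change `(w_after − w_before)/w_before` and the responder / non-responder / excluded partition |
| `wlpred.postprandial` | Trapezoid AUC plus the volatility features `fluc1` (mean absolute difference), `fluc2` (occupied cells of a 10×10 / 50×50 raster of the spline-densified series) and `fluc3` (cells in vertical runs ≥ 2) |
| `wlpred.omics` | 16S/shotgun relative abundances, prevalence + between-visit-variance taxon ranking, binary SNP encoding, sliding-window VIF pruning, weighted genetic risk scores, per-SNP OLS association with covariates and a rank-z normality gate |
| `wlpred.rf` | Fixed-specification random-forest harness: 50 trees, all features per split, min impurity decrease 0.01, 50× shuffle-split stratified 5-fold CV; ROC-AUC / sensitivity / specificity / MCC / PPV / NPV; Gini-importance reports with the 15 % selection-frequency rule |
| `wlpred.selection` | Wrapper forward selection with the shrinking pool-removal schedule (0.4 → … → 0.01 → one-at-a-time) and exhaustive pair/triplet subset search |
| `wlpred.permutation` | Three label-permutation robustness modes and the Gaussianity-gated t-test / Mann-Whitney distribution comparison |
| `wlpred.ensemble` | Model admission at ROC-AUC > 0.62, four scoring schemes (mean, majority vote, confident mean, confident majority) with confidence bands, and classification-threshold sweeps |
| `wlpred.pipeline` / `wlpred.cli` | End-to-end orchestration from a single YAML config; deterministic from one master seed |

## CLI

```bash
wlpred init-config --seed 42 --out config.yaml   # default self-contained config
wlpred simulate --config config.yaml --out sim/  # cohort + feature blocks only
wlpred run --config config.yaml --out run/       # full pipeline + summary
wlpred report run/                               # re-print the summary
wlpred ensemble run/ --method confident_mean --band 0.25,0.75
```

A run directory contains `cohort.tsv`, `labels.tsv`, per-block TSVs,
`metrics.tsv` (mean ROC-AUC / sensitivity / specificity / MCC per data
combination), `model_runs.json` (per-shuffle out-of-fold scores, selected
features, importances), `importance.tsv`, `ensemble_scores.tsv`,
`ensemble_sweep.tsv` and a `manifest.json` recording seeds and warnings.
Ground-truth responder labels from the simulator are written to
`ground_truth.tsv` and never read by the modelling stages.

## Notes

* All randomness flows from a single master seed; identical configs yield
  byte-identical outputs.
* Class-conditional weight changes are drawn from truncated Gaussians whose
  *truncated* moments are matched to the configured means/SDs, so sign
  always agrees with the class and the sample means converge to the
  configured values.
* The test suite scales simulation sizes down (smaller cohorts, lighter
  inner CV) while keeping every statistical assertion and tolerance.
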