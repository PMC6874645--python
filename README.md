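# clinpred

Early-cancer risk prediction from clinical case-report tables.

The pipeline chains four stages on an `n x m` nonnegative patient-by-feature
matrix with a binary outcome label:

1. **Preprocessing** — per-column z-score standardization (population form)
   followed by a min-max rescale to `[0, 1]`, restoring the nonnegativity
   the next stage requires.
2. **NMF** — nonnegative matrix factorization `X ~ W H` by Lee-Seung
   multiplicative updates on the squared Frobenius objective; rows of `W`
   are the reduced `k`-dimensional samples, rows of `H` provide the
   attribute-weight report.
3. **DBN** — a stack of restricted Boltzmann machines pretrained greedily
   with CD-1 contrastive divergence, then fine-tuned end-to-end through a
   sigmoid head on the training labels; the top hidden layer (default width
   4) is the extracted feature matrix.
4. **Linear SVM** — soft-margin dual (SMO-style maximal-violating-pair
   solver) on the DBN features.

Evaluation follows a stratified repeated-split protocol (default 90/10,
100 runs) reporting accuracy, precision, recall, F1 and the false-negative
rate, the metric that matters most for missed diagnoses. A latent-dimension
sweep selects `k` by downstream F1. Because real clinical cohorts of this
kind are private, the package bundles a seeded synthetic-table generator
with planted low-rank structure, mixed binary/continuous feature blocks,
pure-noise columns and strong class imbalance.

## CLI

```sh
# make a synthetic table (270 rows, 50 features, ~10% positives)
clinpred generate --seed 1 --out data.csv

# repeated-split pipeline; writes results.csv, summary.csv, manifest.yaml
clinpred run --data data.csv --config config.yaml --out-dir results/

# latent-dimension sweep over k = 1..20
clinpred sweep --data data.csv --k-max 20 --out-dir sweep/

# attribute-weight report from the factorization
clinpred report --data data.csv --k 14 --out-dir report/
```

`config.yaml` holds `PipelineConfig` fields (`k`, `hidden_sizes`,
`test_fraction`, `n_runs`, `svm_C`, DBN hyperparameters, ...); any omitted
field uses its default. Exit codes: 0 success, 2 configuration error,
1 runtime error.

Note: the default protocol factorizes the full matrix before the
train/test split (leaking unlabeled test-row structure, never labels);
`strict_no_leakage: true` refits NMF per split and projects test rows by
nonnegative least squares.

## Layout

- `src/clinpred/data_model.py` — `SampleTable`, CSV read/write
- `src/clinpred/preprocessing.py` — z-score + nonnegative rescale
- `src/clinpred/nmf.py` — multiplicative-update NMF, k-sweep, weight report
- `src/clinpred/dbn.py` — RBM/CD-1, greedy pretraining, fine-tuning
- `src/clinpred/svm.py` — dual linear SVM
- `src/clinpred/metrics.py` — confusion counts and the five measures
- `src/clinpred/pipeline.py` — orchestration, stratified repeated splits
- `src/clinpred/synthetic.py` — seeded synthetic-table generator
- `src/clinpred/cli.py` — the `clinpred` command
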