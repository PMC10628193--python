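# connpls

Behavioural partial least squares (PLS) for brain connectomes: a tested,
reusable pipeline linking subject-level functional-connectivity edges to a
multi-domain behaviour table, with nonparametric inference, network-level
summaries, spatially constrained annotation correlations, and
connectome-based prediction/classification. Everything runs on synthetic
cohorts with planted ground truth, so no restricted imaging data are needed.

## What it does

- **`connpls.io_model`** — data model (region table, edge matrix, behaviour
  table) with a fixed canonical edge order (row-major upper triangle,
  0-based), TSV/JSON readers and writers, id-based subject alignment.
- **`connpls.synthetic`** — cohorts whose edge and behaviour blocks share one
  planted latent dimension of configurable strength, with optional confound
  contamination; spatially autocorrelated annotation maps over region
  centroids; two-group cohorts shifted along the latent dimension.
- **`connpls.connectome`** — Pearson correlation matrices from parcellated
  time series, Fisher r-to-z, upper-triangle (de)vectorization.
- **`connpls.preprocess`** — OLS confound residualization plus
  standardization with strict fit-on-train / apply-on-test separation, and
  rank-based quantile normalization.
- **`connpls.pls`** — SVD of the cross-correlation matrix, saliences,
  composite scores, loadings; permutation tests (rank-matched singular
  values, BH-FDR), bootstrap loading SDs and z-scores, leakage-safe repeated
  k-fold cross-validation, cross-dataset projection, model comparison, PCA
  comparison.
- **`connpls.network`** — BH thresholding of edge loadings, signed
  count/percentage summaries, within/between-network block averages, signed
  weighted-degree region importance and top-k nodes.
- **`connpls.annotation`** — Spearman/Pearson correlation of region
  importance against per-region annotation maps, with variogram-matching
  surrogate nulls that preserve the value multiset exactly while matching
  spatial autocorrelation.
- **`connpls.prediction`** — nested-CV support-vector regression and
  RBF-SVM classification with repetition averaging and label-permutation
  significance; masked vs whole-brain feature-set comparison.
- **`connpls.cli`** — one entry point wiring the stages together with a
  validated YAML configuration and provenance metadata in every artifact.

## CLI

```sh
# write a synthetic cohort with a strong planted latent dimension
connpls simulate --out run/ --seed 1 --n 200 --n-regions 10 --n-behav 8 \
    --strength 0.8 --shift 2.5

# build an edge matrix from per-subject time-series TSVs
connpls build-fc sub1.tsv sub2.tsv --out edges.tsv

# run the full pipeline from a config file
connpls run-all --config config.yaml --seed 1
```

A minimal `config.yaml`:

```yaml
out_dir: run
seed: 1
simulate: {n_subjects: 200, n_regions: 10, n_behav: 8, latent_strength: 0.8}
n_perm: 1000
n_boot: 1000
folds: 10
repetitions: 200
stages: {simulate: true, fit: true, validate: true, summarize: true, annotate: true}
```

Single stages (`connpls fit`, `validate`, `summarize`, `annotate`,
`predict`, `classify`) re-use artifacts already present in `out_dir`.

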