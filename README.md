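# progsig

A comparison framework for prognostic gene-expression signature methods.
It implements five feature-selection approaches spanning three families —

| family      | method       | features ranked          | classification feature value            |
|-------------|--------------|--------------------------|-----------------------------------------|
| single-gene | `mod_t`      | genes, by moderated-t p  | the gene's expression value             |
| gene-set    | `median_set` | hub gene-sets, by p      | per-sample median over set members      |
| network     | `netrank`    | genes, by damped network propagation of \|expression–survival correlation\| | the gene's expression value |
| network     | `taylor`     | hub sub-networks, by mean \|Δ within-class edge correlation\| | hub − interactor expression difference per edge |
| network     | `bss_wss`    | hub sub-networks, by BSS/WSS of per-edge within-class correlations | the hub gene's expression value |

— and evaluates them with three classifiers (from-scratch DLDA, and seeded
random-forest / linear-SVM adapters) under repeated stratified 5-fold
cross-validation with strictly in-fold feature selection.  Three evaluation
layers are produced: overall and class-specific error, feature-selection
stability (mean pairwise top-n overlap across all CV folds), and
patient-level accuracy (per sample, the fraction of CV rounds classified
correctly, with easy / hard / differential categorisation).

A synthetic-data module generates scale-free-ish PPI networks with planted
hubs plus two-class expression matrices carrying planted differentially
expressed genes, differentially expressed gene-sets, and correlation-flip
hub sub-networks, together with class-separated survival times and a
ground-truth manifest — so the entire pipeline is testable offline.

## Input formats

* **Expression**: TSV, header `gene_id<TAB>S1<TAB>S2...`, one row per gene,
  log-scale numeric values.  Duplicate gene rows keep the highest-variance
  row (warned); missing values are rejected.
* **Phenotype**: TSV with header `sample_id<TAB>class<TAB>survival_time`;
  class is `GP`/`PP` (case-insensitive), survival in years.
* **Network**: two-column TSV edge list, or three-column SIF
  (`geneA<TAB>pp<TAB>geneB`, middle column ignored).  Undirected,
  deduplicated, self-loops dropped.

`progsig.io_data.align` restricts the three inputs to a shared gene and
sample universe (expression column order is canonical).

## CLI

```bash
# generate a synthetic dataset
progsig simulate --config cfg.yaml --out dataset/

# run a full comparison from a YAML config
progsig run --config cfg.yaml

# recompute tables from a finished run directory
progsig stability --run-dir progsig_run
progsig report --run-dir progsig_run --heatmap
```

Minimal `cfg.yaml`:

```yaml
methods: [mod_t, median_set, netrank, taylor, bss_wss]
classifiers: [dlda, rf, svm]
rounds: 100
k: 5
n_features: 50          # or a per-method mapping
netrank: {a: 0.3}
seed: 1
simulate: {}            # default simulation; or use data: {expression: ..., phenotype: ..., network: ...}
out_dir: progsig_run
```

`progsig run` writes `errors.csv`, `class_errors.csv`, `stability.csv`,
`patient_matrix.csv`, `patients_categorized.csv`, raw
`predictions.csv`/`selections.csv`, `run.log` and a `manifest.json`
(config + expanded per-component seeds + versions) sufficient to reproduce
the run.  Everything is deterministic given the master seed.

## Package layout

```
src/progsig/
  io_data.py            # formats, validation, alignment
  network.py            # PPI graph, hubs, hub sub-networks, gene-sets
  feature_selection.py  # the five ranking methods
  feature_matrix.py     # per-sample classification feature builders
  classifiers.py        # DLDA (from scratch) + RF/SVM adapters
  evaluation.py         # CV engine, errors, stability, patient-level accuracy
  synthetic_data.py     # planted-signal generator + on-disk round trip
  config.py, cli.py     # YAML config validation and the progsig CLI
```
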