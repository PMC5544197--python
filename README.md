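# ranksig

Rank-signature classification of two-group expression cohorts.

Each sample is summarized by a rank-based signature — the `s` highest- and
`s` lowest-ranked probes of its expression profile. Samples are compared
all-to-all with a distance built from weighted running-sum enrichment
scores (how extreme one sample's signature sits inside another sample's
ranking), and a test sample is assigned to the class whose members have
the lowest averaged distance to it. Around this core the package provides:

- **Cross-validated accuracy** (stratified k-fold) and an empirical
  **probe-label permutation test** with the add-one `(r+1)/(B+1)` p-value.
- A **genetic optimizer** over (signature size, probe inclusion mask) that
  searches a candidate pool of top-ranked probes for the best-classifying
  signature configuration.
- **Biomarker extraction** as the union of all per-sample signature probes,
  with per-probe log2 fold-changes and exact rank-sum p-values.
- A **pathway-restricted ("reverse") search** that asks whether the probes
  of one gene set alone can classify the cohort.
- **Over-representation analysis**: upper-tail hypergeometric tests with
  step-down Bonferroni (Holm) adjustment, counted at gene level.
- **HOMA-IR cohort selection**: extreme-group selection inside a BMI
  window with a greedy covariate-matching pass.
- A seeded **synthetic-data generator** emulating a two-color microarray
  log-ratio design (planted differential probes, gene-set structure with a
  designated enriched set, clinical covariates) so the whole pipeline is
  testable offline.

All file formats are plain text: TSV expression matrices, GMT gene sets,
two-column probe→gene maps, CSV clinical tables, JSON reports.

## Command line

```sh
# emit a synthetic cohort (matrix, labels, GMT, probe map, clinical, truth)
ranksig simulate --n-probes 2000 --n-diff 40 --log2fc 2.0 --seed 1 --outdir sim/

# cross-validated classification accuracy
ranksig classify sim/matrix.tsv sim/labels.tsv -s 50 --folds 5 --seed 1

# permutation test of the accuracy (B permutations)
ranksig permtest sim/matrix.tsv sim/labels.tsv -s 50 -B 100 --seed 1

# GA-optimized biomarker discovery
ranksig biomarker sim/matrix.tsv sim/labels.tsv --probe-map sim/probe_map.tsv \
    --pool-size 50 --out biomarker.tsv

# hypergeometric over-representation of a gene list
ranksig ora genes.txt sim/gene_sets.gmt --probe-map sim/probe_map.tsv --out ora.tsv

# reverse-mode search restricted to one gene set
ranksig restrict sim/matrix.tsv sim/labels.tsv SET001 \
    --gmt sim/gene_sets.gmt --probe-map sim/probe_map.tsv --out restricted.tsv

# HOMA-IR extreme-group selection from a clinical CSV
ranksig select-groups clinical.csv --bmi-high 25.0 --n-per-group 10 --out groups.json

# figure-data exports (heatmap rank matrix, similarity network)
ranksig export sim/matrix.tsv sim/labels.tsv --biomarker-tsv biomarker.tsv --outdir fig/

# full pipeline from a YAML config, with provenance manifest
ranksig run-all config.yaml --outdir run/
```

A minimal `config.yaml` for `run-all`:

```yaml
seed: 1
simulate:
  n_probes: 500
  n_per_group: 10
  n_diff_probes: 10
  log2fc: 2.0
  noise_sd: 0.2
ga: {population_size: 30, generations: 10, pool_size: 12, s_min: 5, s_max: 6, init_density: 1.0}
cv: {k: 5}
permutations: 100
```

Instead of `simulate:`, real inputs can be supplied as
`inputs: {matrix: ..., labels: ..., gene_sets: ..., probe_map: ...}`.

## Notes on method choices

- The enrichment-score hit weight is `|rank − (N+1)/2|^p` with `p = 1` by
  default; `p = 0` recovers the unweighted Kolmogorov–Smirnov form.
- Distances are symmetrized by averaging the two directed similarities and
  mapped to `[0, 2]` via `1 − similarity`; any affine rescaling leaves the
  argmin classification unchanged.
- The permutation null shuffles value-to-probe assignment independently
  within every sample — a single global relabeling provably leaves all
  distances unchanged and cannot form a null.
- In `discover_biomarker` the permutation test runs on the input matrix,
  not the GA-selected probes, because permuting only a selection-optimized
  subset against selection-free nulls is anti-conservative.
- Feature selection can run once on all data (`--global-selection`, default)
  or inside every training fold (`--nested-selection`) for leakage-free
  accuracy.
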