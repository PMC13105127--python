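# spatialtx

Analysis toolkit for targeted-panel spatial transcriptomics (CosMx-like
~960-gene panels, sparse per-cell counts) covering five pipeline stages plus a
synthetic data generator:

- **`spatialtx.io_model`** — the shared data model (`SpatialDataset`: sparse
  cells × genes counts, coordinates, cell type / patient / timepoint labels)
  and readers/writers for MatrixMarket counts, BED-derived probe and gene
  interval files, and ligand-receptor pair tables.
- **`spatialtx.synth`** — seeded generator of CosMx-like datasets with planted
  copy-number events, Dirichlet-multinomial topic structure, Gaussian spatial
  blobs, log-normal library sizes (optionally tied to a depth-confounding
  latent axis), and timepoint-specific ligand-receptor shifts.
- **`spatialtx.spatial_cna`** — expression-based copy-number calling on
  targeted panels: per-cell probe z-scores against a diploid baseline of
  non-malignant lineages, loss-probe inversion, Bonferroni-corrected rank-sum
  probe validation with effect-size and direction gates, and a two-component
  unequal-variance Gaussian-mixture split of per-cell burden scores.
- **`spatialtx.topics`** — CLR-normalized collapsed-Gibbs LDA (cells as
  documents, genes as words; α = 50 total / β = 0.1 / 500 iterations / 250
  burn-in defaults), held-out-perplexity topic-number selection by the
  maximum-curvature elbow rule, and spatial integration via proximity scores
  to k-means tissue centroids appended as pseudo-genes, with topic
  classification into gene-restricted / spatial-restricted /
  spatially-integrated.
- **`spatialtx.programs`** — Louvain clustering of topics (kNN graph on
  gene-topic columns, k = 5, resolution 0.9) and per patient-timepoint
  abundance proportions (the alluvial-plot computation).
- **`spatialtx.lr`** — ligand-receptor scores per sender→receiver context
  (product of mean log-normalized expression, minimum 10 cells per group,
  count-weighted multi-lineage pooling) and waterfall ranking of
  log2 fold changes between biopsies (pseudocount 0.001).
- **`spatialtx.bench`** — the coverage-purity benchmark: equal-frequency
  total-count quintile bins, Louvain clustering of a latent space, and
  cluster-size-weighted modal-bin purity, used to compare topic embeddings
  against a scaled-PCA comparator under depth confounding.

## CLI

All stages are subcommands of one entry point:

```bash
spatialtx simulate --config cfg.yaml --out data/
spatialtx cna-call --data data/ --probes probes.bed --genes genes.bed \
    --reference-types Fibroblast,Immune --candidate-types Malignant --out cna/
spatialtx topics-fit --data data/ --k 30 --seed 7 --out topics/     # or --select 10:100:10
spatialtx topics-cluster --topics topics/ --meta data/cells.tsv --out programs/
spatialtx lr-score --data data/ --pairs pairs.tsv --early T1 --late T2 --out lr/
spatialtx bench-purity --data data/ --topics topics/ --out bench/
```

File formats: counts as MatrixMarket coordinate MTX with `genes.tsv` /
`cells.tsv` sidecars; probe and gene intervals as headerless BED-derived TSVs
(0-based half-open, `chr`-prefixed); LR pairs as a `ligand receptor source`
TSV. See module docstrings for column details.

## Notes on conventions

- The count filter (`filter_min_counts`, default 200) is inclusive and is a
  pipeline stage, not a hard-wired default applied everywhere.
- The rank-sum effect size defaults to r = |Z|/√N; Cohen's d is also reported
  and can be used as the validation gate instead.
- The CLR→token bridge for LDA (clip negatives, ×10, round half-up) and the
  topic-class thresholds are documented package conventions, configurable in
  the API.
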