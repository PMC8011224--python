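# sexlabel

Expression-based sample sex labeling for transcriptomic corpora, with
misannotation (sample-swap) detection, metadata entity normalization, and
sex-bias summary statistics. Every stage is testable offline against
synthetic corpora with known ground truth.

## What it does

- **synthgen** — generates synthetic expression + metadata corpora
  (bimodal Y-gene expression by sex, elevated X-escape expression in
  females, per-study batch shifts, platforms, pooled samples, cell lines
  with Y loss, metadata missingness and injected label swaps), plus
  cell-line/drug lexicon fixtures. Ground truth is written to a separate
  file that pipeline stages never read.
- **meta_labels** — extracts sex labels from metadata key/value pairs
  (keys mentioning sex/gender; whole-word male/female value matches) and
  assigns each study one of six categories (unlabeled, female-only,
  male-only, mostly-female, mostly-male, mixed).
- **preprocess** — removes RNA-seq samples with fewer than 100,000 total
  counts and Box-Cox transforms count data per gene (microarray input
  passes through).
- **sexinfer** — elastic-net logistic regression over X/Y-chromosome genes
  producing P(male) scores, fitted with study-group-stratified nested
  cross-validation (lambda-1se inner selection, median-error alpha
  selection — the percentile rule at the 50th percentile). Labels are
  assigned outside the open (0.3, 0.7) band at the default 0.7 threshold;
  includes threshold sweeps and per-platform QC with a 70% concordance
  floor.
- **mislabel** — three misannotation estimates: single- vs mixed-sex
  mismatch rates with a chi-squared comparison; conservative consensus
  across multiple labelers; and per-study Gaussian-mixture clustering of
  sex scores (unequal variances, variance prior scale 0.15, optional
  uniform noise over the unclassified band, BIC model selection, 0.3
  separation filter, 0.95 posterior cutoff for match/mismatch flags).
- **entities** — cell-line and drug lexicon construction (duplicate-name,
  punctuation-variant, and synonym/name-collision rules; numeric/short/
  stop-word term removal), three-tier attribute mapping with n-gram
  (n = 1..3) matching, source-type classification, and drug-mention vs
  drug-exposure study labeling with an 18-term control vocabulary.
- **bias** — sex-breakdown tables, cell-line donor-vs-inferred switch
  rates and per-line profiles, Spearman correlation of median scores vs
  copy number, per-ATC-class chi-squared enrichment with 0.05/48
  Bonferroni, and per-drug sex profiles (2/3–1/3 bias rule).
- **pipeline / cli** — YAML-configured end-to-end driver with per-stage
  derived seeds, structured logging, config-hash-stamped outputs and a
  run manifest.

## CLI

All commands are subcommands of `sexlabel`:

```sh
sexlabel simulate --config sim.yaml --out corpus/ --seed 1
sexlabel label-meta --meta corpus/meta.tsv --out labels/
sexlabel preprocess --expr expr.tsv --type rnaseq --min-counts 100000 --out expr_bc.tsv
sexlabel train --expr corpus/expr.tsv --meta corpus/meta.tsv \
    --genes corpus/genes.tsv --seed 1 --out model.json
sexlabel predict --model model.json --expr corpus/expr.tsv --out scores.tsv
sexlabel qc-platforms --scores scores.tsv --meta corpus/meta.tsv --out platforms.tsv
sexlabel flag-swaps --scores scores.tsv --meta corpus/meta.tsv \
    --posterior 0.95 --min-sep 0.3 --seed 1 --out swaps/
sexlabel map-cells --meta corpus/meta.tsv --lexicon cells.tsv --out cellmap.tsv
sexlabel map-drugs --study-meta studies.tsv --sample-meta samples.tsv \
    --lexicon drugs.tsv --out drugmap/
sexlabel bias --scores scores.tsv --studies labels/study_categories.tsv --out bias/
sexlabel run --config pipeline.yaml
```

File formats are plain TSV (expression optionally matrix-market); the
fitted model serializes to JSON.

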