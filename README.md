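# caf-atlas

Analysis pipeline for fibroblast subtypes in skin cancer, combining
Smart-seq2 single-cell expression processing with in-situ ROI
quantification. The package implements:

- **`caf_atlas.qc`** — cell-quality filtering (≥ 400 detected genes, total
  RPKM within the inclusive interval [150,000, 8,000,000]) and
  library-size log-normalization (`ln(1 + v / total × 10⁴)`).
- **`caf_atlas.cnv`** — reference-anchored copy-number profiles over
  genomically ordered genes (expression clip ±1, 101-gene moving average
  within chromosomes, per-cell median recentering), SoS scoring (mean of
  squared estimates), Pearson correlation to a per-sample malignant
  reference built from top-SoS cells, and a three-way quadrant call
  (keratinocyte cutoffs r ≥ 0.45 / SoS ≥ 0.017; melanocyte r ≥ 0.40 /
  SoS ≥ 0.026), plus PTCH1/PTCH2-high flagging.
- **`caf_atlas.markers`** — Wilcoxon rank-sum marker signatures per cluster
  with BH correction, and bin-matched module scores (24 expression bins,
  100 control genes per set gene, seeded) compared by rank-sum tests.
- **`caf_atlas.rl`** — permutation receptor–ligand enrichment: candidate
  pairs from cluster signatures against a ligand/receptor database,
  equally-sized random pools resampled from the database universes
  (10,000 replicates, counter-based per-replicate seeding), add-one
  empirical p-values, a ≥ 2.5 % donor co-presence prerequisite per cluster
  pair, and one-family BH correction.
- **`caf_atlas.spatial`** — CAF phenotyping from marker positivity
  (totalCAF COL1A1+; iCAF COL1A1+MMP1+; mCAF COL1A1+COL11A1+MMP1−),
  pooled ROI densities (Σcounts/Σarea, ≥ 5 ROIs per sample), two-sided
  Mann-Whitney class comparisons, log–log T-cell-exclusion regression and
  high/low density stratification with t-tests.
- **`caf_atlas.synthetic`** — multi-donor atlas and ROI-table generators
  with planted markers, CNV segments, ligand–receptor circuits and
  exclusion effects, giving exact ground truth for every stage.

## CLI

```bash
caf-atlas make-demo --seed 1 --out demo/      # synthetic fixture + config
caf-atlas run --config demo/demo.yaml --out demo/results
caf-atlas qc --matrix demo/fixture --out filtered/
caf-atlas cnv --matrix demo/fixture --reference-label stromal \
    --lineage keratinocyte --out cnv_calls.tsv
caf-atlas markers --matrix demo/fixture --cluster iCAF --out sig_iCAF.tsv
caf-atlas rl --matrix demo/fixture --db demo/lrdb.csv --seed 7 \
    --out interactions.tsv
caf-atlas spatial --roi demo/rois.csv \
    --compare "nodular BCC,infiltrative BCC" --phenotype iCAF --out stats.tsv
```

`caf-atlas run` executes qc → cnv → markers → rl → spatial (stages are
independently skippable via the config) and writes a `manifest.json`
recording parameters, seed, input checksums and per-stage row counts.
Identical config + seed gives byte-identical outputs.

### Fixture formats

Matrices are MatrixMarket (`matrix.mtx` + `genes.tsv`/`cells.tsv`, genes ×
cells) or dense TSV (genes × cells); cell metadata is a TSV with columns
`cell_id, donor, sample, lineage, cluster`; gene positions are a BED-like
TSV (`chrom, start, end, gene_symbol`); the ligand–receptor database is a
CSV with `ligand, receptor[, source]` columns; ROI tables are CSVs with
`sample_id, tumor_class, roi_id, area_mm2` plus per-phenotype count
columns and optional `cd3_in_nest_count` / `nest_area_mm2`.

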