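# ccimap

Ternary cell-identity mapping and confused-cell-identity (CCI) scoring for
squamous epithelial transcriptomes.

Cells (or bulk samples) are scored against three normal-lineage gene
signatures — basal stem (BS), proliferating basal keratinocyte (BK) and
differentiated keratinocyte (DK) — and projected into the BS–BK–DK
barycentric simplex. The angle between a cell's score vector (a, b, c) and
each axis has cosine `coord / sqrt(a² + b² + c²)`; the CCI score is
`f / sd(cos θ1, cos θ2, cos θ3)` (sample sd, configurable `f`, default 10),
so it is maximal for cells equally similar to all three lineages and
minimal at the corners. The package covers the full workflow:

- **`ccimap.io_qc`** — 10x-style MatrixMarket triplet and dense TSV/CSV
  readers/writers, GMT gene sets, metadata validation, QC filtering
  (detected genes per cell in [200, 7500], mito fraction ≤ 20%, gene seen
  in ≥ 3 cells; strict bounds) and per-cell log normalization.
- **`ccimap.markers`** — one-vs-rest marker calling (expm1-scale natural-log
  fold change, pct1/pct2 detection fractions, tie-corrected rank-sum test,
  BH adjustment), lineage-signature selection (`pct2 < 0.4`) and
  cross-cohort progression signatures.
- **`ccimap.cci`** — signature scoring, ternary projection, CCI scores,
  the ECDF-vs-fitted-logistic positivity cut-point, CCI signature genes
  (fold change > 0.25, base mean > 0.8, pct1 > 0.8) and ternary
  kernel-density export.
- **`ccimap.stats`** — score/signature correlation, two-group tests,
  hypergeometric overlap, maximally selected log-rank cut-points (with a
  fast permutation null) and Kaplan–Meier / log-rank stratification.
- **`ccimap.simulate`** — a seeded synthetic-cohort generator (three pure
  corner populations plus a confused malignant population with planted
  malignant-only genes; negative-binomial counts, dropout, library-size
  variation, stage labels) and a survival-cohort generator with a planted
  hazard cut-point.
- **`ccimap.cli`** — the pipeline as subcommands.

## CLI

Every stage writes plain TSV/GMT/JSON under `--outdir` and records its
parameters in a `<stage>_summary.json`. A complete run on synthetic data:

```sh
ccimap simulate  --outdir out/sim --seed 1
ccimap qc        --matrix out/sim/matrix --outdir out/qc
ccimap signatures --matrix out/qc/lognorm.tsv --format dense_table \
                 --metadata out/sim/metadata.tsv --outdir out/signatures
ccimap score     --matrix out/qc/lognorm.tsv --format dense_table \
                 --gmt out/signatures/lineage_signatures.gmt --outdir out/score
ccimap cci-genes --matrix out/qc/lognorm.tsv --format dense_table \
                 --cci-table out/score/cci_table.tsv \
                 --metadata out/sim/metadata.tsv --outdir out/cci_genes
ccimap survival  --simulate-n 400 --seed 1 --outdir out/surv
```

or, end to end in one command, `ccimap report --outdir out --seed 1`.

Key outputs: `cci_table.tsv` (per-observation scores a/b/c, barycentric
coordinates, cosines, sd, CCI, positivity, cohort cut-point — axis order is
always BS, BK, DK), `lineage_signatures.gmt`, `cci_signature.gmt`,
`ternary_density.tsv` (with `--density`), `survival_groups.tsv`. Relevant
flags: `--f`, `--epsilon`, `--sd-mode {sample,population}`, `--bins`,
`--min-logfc` (0.25 default; 0.2 variant supported), `--background
{all_se,malignant_only}`, `--mode {maxstat,median}`.

The maxstat survival p-value is post-selection and reported as descriptive
only.

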