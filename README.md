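# ribodrop

Synthetic-data analysis toolkit for RNA-binding-protein condensate biology.
It bundles, in one reproducible pipeline, the quantitative workflows used to
study how an RNA-binding protein (e.g. FUS) affects the translatome and how
its phase-separated condensates sequester client proteins (e.g. FMRP):

- **Translatome differential expression** — negative-binomial Wald test with
  median-of-ratios size factors, moderated method-of-moments dispersions,
  Benjamini–Hochberg FDR and signed z-scores (`ribodrop.de`).
- **Target shift analysis** — CLIP-peak annotation against gene models
  (0-based, half-open, strand-aware), mature-RNA target selection,
  expression-matched target/non-target sets and a two-sample
  Kolmogorov–Smirnov test on signed z ECDFs (`ribodrop.shift`).
- **Droplet partitioning** — Otsu segmentation of condensate images,
  circularity/size particle gates, background estimation from random
  droplet-free 5 µm ROIs and per-droplet client enrichment ratios
  (`ribodrop.droplets`).
- **In-vitro kinetics** — windowed initial-rate fits for turbidity and
  in-vitro-translation time courses, control normalization and apparent
  saturation-concentration (Csat) estimation by x-intercept
  (`ribodrop.kinetics`).
- **Axonal puncta** — puncta detection with a size gate, linear density per
  100 µm of traced axon and full/partial/negative two-channel overlap
  classification (`ribodrop.puncta`).
- **Synthetic data generators with planted ground truth** for every assay
  (`ribodrop.sim`), so each analysis can be validated by recovery of known
  effects rather than by eye.

Every generator takes an explicit seed and every analysis is deterministic,
so full pipeline runs are byte-for-byte reproducible.

## Worked example

```python
import numpy as np
from ribodrop import de, droplets, shift, sim

# 1. translatome contrast with a planted 2-fold target depletion
cfg = sim.SimCountConfig(n_genes=2000, target_fraction=0.2, target_log2fc=-1.0, seed=1)
counts, truth = sim.simulate_counts(cfg)
table = de.nb_wald_test(counts)
targets = set(truth.loc[truth.is_target, "gene"])
result, curves = shift.cumulative_shift(table, targets)
print(f"significant at padj<0.1: {(table.padj < 0.1).sum()} / {len(table)}")
print(f"KS D = {result.D:.3f}, p = {result.p:.3g}, direction = {result.direction}")

# 2. droplet partition ratio from a synthetic two-channel field
field_cfg = sim.SimDropletConfig(seed=1)          # planted client ratio 3.5
raster, planted = sim.simulate_droplet_field(field_cfg)
records, enrich = droplets.quantify_partition(raster, seed=1)
print(f"droplets kept: {enrich.n_droplets}, mean client ratio = {enrich.mean_ratio:.2f}")
```

Output:

```text
significant at padj<0.1: 508 / 2000
KS D = 0.983, p = 3.66e-169, direction = down
droplets kept: 25, mean client ratio = 3.35
```

The 400 planted target genes dominate the significant set, the target z-score
ECDF is shifted strongly to the left (direction `down`), and the recovered
mean partition ratio (3.35) is within 5 % of the planted 3.5.

## Command line

The `ribodrop` entry point wraps the same functions:

```bash
ribodrop simulate counts --seed 1 --out sim/          # counts + design + truth
ribodrop de --counts sim/counts.tsv --design sim/design.tsv --out de.tsv
ribodrop run-all --config config.yaml --seed 1 --out run/   # full pipeline
```

`run-all` executes counts → DE → shift → droplets → kinetics → axon stages,
writes TSV/JSON artifacts plus a manifest, and reproduces identical tables
for identical config + seed. Unknown configuration keys are rejected.

## Testing

```bash
python -m pytest -q tests/
```

The suite (150 tests) combines unit tests, property-based tests (hypothesis)
and acceptance tests that check the analyses against independent brute-force
oracles (O(n²) KS statistic, all-pairs interval overlap, exhaustive Otsu
threshold search, closed-form OLS) and against planted ground truth (null
p-value calibration, shift direction recovery, partition-ratio and
puncta-composition recovery, byte-identical pipeline reruns).

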