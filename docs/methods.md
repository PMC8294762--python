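# Methods

This note documents the statistical models, the parameter defaults and their
rationale, what the synthetic-data generators do and do not emulate, the
numerical conventions, and known limitations.

## Count model and differential expression

Counts are modelled as negative binomial with mean μ and variance μ + αμ²,
simulated exactly as a gamma–Poisson mixture (gene-wise gamma with shape 1/α
scaled by μ, then Poisson). Per-gene base means are log10-normal
(mean 3.0, sd 0.8 in log10 units, ~2 000 genes, 5 vs 5 samples,
dispersion α = 0.05 by default), matching the scale of a typical bulk
RiboTag/translatome library after filtering. Sample-specific size factors are
drawn uniformly from [0.7, 1.4] and applied multiplicatively. A configurable
fraction of genes (default 20 %) carries a planted log2 fold change
(default −1.0, i.e. 2-fold depletion of targets in the mutant group).

The test is a self-contained negative-binomial Wald test, intentionally
simpler than DESeq2:

- **Size factors**: median-of-ratios against the geometric-mean reference
  gene-wise, rescaled so their geometric mean is 1.
- **Dispersion**: per-gene method-of-moments on normalized counts, floored at
  1e−8, then moderated toward the across-gene mean dispersion with a prior
  weight of `dispersion_prior_df = 25` effective degrees of freedom:
  α = (df·α_gene + 25·ᾱ)/(df + 25). With 5 + 5 samples the raw
  method-of-moments estimator is noisy enough to make the Wald p-values
  anticonservative under the null; in simulations at the defaults the raw
  estimator fails a Kolmogorov–Smirnov test against U(0,1) decisively, while
  the moderated estimator passes and keeps the fraction of genes at
  padj < 0.1 under the null at ≈ 1 %. The moderation is a simple
  empirical-Bayes squeeze, not the full DESeq2/edgeR machinery; setting
  `dispersion_prior_df = 0` recovers the raw tagwise estimator.
- **Effect and test**: log2FC = log2((μ_mut + c)/(μ_ctl + c)) with
  pseudocount c = 0.5 (stabilizes low-count genes); the standard error comes
  from the delta method on the NB group-mean variances; the p-value is
  two-sided normal. No Cook's-distance filtering and no LFC shrinkage.
- **Multiple testing**: Benjamini–Hochberg step-up FDR.
- **Signed z**: z = sign(log2FC)·Φ⁻¹(1 − p/2) with p floored at 1e−300 so
  the quantile is finite.

`compare_contrasts` merges two DE tables on shared genes, reports the Pearson
correlation of signed z, and classifies each gene as significant in both /
one / neither contrast at padj < 0.1 (equality counts as non-significant).

## Target shift analysis

CLIP peaks (BED-style, 0-based half-open) are annotated against gene-model
intervals (stored 1-based inclusive on disk, converted on read) by a
per-chromosome sorted sweep; a hit requires ≥ 1 bp overlap and strand
compatibility (strands must match only when both records are stranded).
Target genes are, by default, genes with at least one peak in a mature-RNA
region (5′ UTR, CDS, 3′ UTR); intron-only genes are excluded
(`mode="any"` keeps them).

Targets and non-targets are compared only inside a strict expression window,
2.5 < log10(baseMean) < 4.25 by default, so that the comparison is
expression-matched and not driven by low-count noise or a handful of very
abundant genes; both bounds are exclusive. The statistic is the two-sample
Kolmogorov–Smirnov D between the signed-z ECDFs, computed exactly on the
pooled sample points, with the classical asymptotic p-value
(`kolmogorov(√(n_x n_y/(n_x+n_y))·D)`), adequate at the hundreds-of-genes
scale used here. The reported direction is `down`/`up` when p < 0.05 and the
median z difference is negative/positive, `none` otherwise.

## Droplet partitioning

Synthetic fields are 100 × 100 µm at 0.2 µm/pixel with 25 non-overlapping
disks (radius 1.5–4 µm, ≥ 1 µm gaps), a bright scaffold channel
(400 inside / 50 outside) for segmentation, a client channel with a planted
partition ratio (inside/outside intensity, default 350/100 = 3.5), a 1-pixel
Gaussian blur and additive Gaussian noise (σ = 5, i.e. SNR 20 against the
client background). There is no point-spread-function model beyond the blur:
the goal is recovery of planted ratios, not optics realism.

Analysis: optional blank subtraction (clamped at 0); Otsu threshold on a
256-bin histogram (constant images are rejected); 8-connected components;
per-particle area, equivalent radius, Crofton perimeter and circularity
4πA/P² clamped to ≤ 1 (Crofton is less biased than pixel-edge counting for
small disks, but discretization can still push circularity slightly above 1).
Particles are kept when radius > 1 µm and circularity ∈ [0.5, 1.0] —
droplets are round; debris and merged segments are not. Background is the
mean of 5 randomly placed (seeded) droplet-free circular ROIs of 5 µm
diameter, mirroring the manual droplet-free-ROI convention; averaging several
ROIs reduces the variance of the estimate without touching the droplet mask.
The enrichment ratio is mean client intensity inside each droplet divided by
the client background mean; the summary is the arithmetic mean over droplets.
The scaffold channel defines the masks; client enrichment is measured within
them (configurable).

## In-vitro kinetics

Time courses follow a saturating exponential
s(t) = plateau·(1 − exp(−k·t/plateau)), whose initial slope is exactly k.
Turbidity defaults: k = 0.005 OD/min, plateau 0.5 OD, one reading every
35 s for 20 min starting at t = 0, noise σ = 0.002 OD. Translation
(luminescence) defaults: readings at 10–50 min. Noise is Gaussian truncated
at ±5σ so that a pathological draw cannot dominate a short fitting window.

Initial rates are ordinary-least-squares slopes; turbidity fits use the
[0, 5] min window (9 points), where the curvature bias of the saturating
model at the default parameters is ≈ 2 % — well inside the noise-driven
variability of a single fit. Rates are normalized per plate by the mean
control ("buffer") rate, so the control maps to 1 by construction.

Apparent Csat is estimated from rate-vs-concentration data: points above a
noise floor (default 3 × the SD of the lowest-concentration replicates, or a
user-supplied value) are fit by OLS and Csat is the x-intercept, clamped at
0; at least 3 above-floor concentrations are required, all-flat data raise an
error ("no transition"), and estimates outside the tested concentration range
are flagged `extrapolated`.

## Axonal puncta

Synthetic axons are straight horizontal corridors (2 µm wide, 0.1 µm/pixel,
2 µm dark margins) with a deterministic number of planted ch1 puncta —
round(density × length/100), default 10 per 100 µm — with areas uniform in
0.15–0.45 µm². Each ch1 punctum carries a known overlap class: `full` gets a
concentric ch2 partner 1.2× its radius (overlap fraction 1), `partial` an
equal-radius partner offset by one radius (overlap fraction ≈ 0.39 for equal
disks), `negative` no touching ch2 signal; remaining ch2 puncta are placed
clear of every ch1 punctum so planted classes stay exact. Default
composition: 20 % full, 40 % partial, 40 % negative.

Detection is Otsu + 8-connected components with a minimum-contrast guard:
because an Otsu threshold always splits the histogram, a field whose
"foreground" does not exceed the background by ≥ 3 background standard
deviations is reported empty. The size gate keeps areas in
[0.05, 3.00] µm², inclusive — interpreted as area (µm²) since punctum sizes
are reported in µm² throughout. Linear density counts puncta whose centroid
lies within half the corridor width of the traced axon polyline, × 100 /
polyline arc length (puncta per 100 µm). Overlap classification thresholds
the fraction of a punctum's area covered by the other channel's mask:
≥ 0.80 `full`, ≤ 0.05 `negative`, otherwise `partial`; the thresholds are
exposed because these classes are usually defined pictorially.

Group summaries scale every axon's density by 100/mean(control) so the
control group averages 100, and report mean ± SEM with a Kruskal–Wallis test
across groups plus pairwise two-sided Mann–Whitney tests against the control,
BH-adjusted (a rank-based post-hoc in place of Dunn's test, which needs no
extra dependency and controls FDR across the pairwise comparisons).

## Pipeline and numerics

`run-all` executes counts → DE → shift → droplets → kinetics → axon. Each
stage derives its seed from the global seed by hashing `"{seed}:{stage}"`
with SHA-256 and reducing modulo 2³¹, so stages are statistically independent
and adding a stage never perturbs another stage's stream. All randomness
flows through `numpy.random.default_rng`; identical config + seed reproduce
byte-identical TSV/JSON tables (the manifest records wall-clock timing and is
excluded from that guarantee). Configuration is strict YAML: unknown keys are
errors, never silently ignored.

Numerical conventions: pseudocount 0.5 in log2FC; p-values floored at 1e−300
before inverse-normal transforms; dispersions floored at 1e−8; circularity
clamped at 1; Otsu on 256 bins (on tie plateaus any maximizing bin is a valid
threshold); background ROI placement is rejection-sampled with a bounded
attempt count.

## Limitations

- The DE test is a deliberately minimal NB Wald stand-in: no GLM with
  covariates, no Cook's filtering, no LFC shrinkage; it is calibrated at the
  simulated defaults but not a DESeq2 replacement on real libraries.
- The KS p-value is asymptotic; for very small gene sets an exact or
  permutation p would be preferable.
- Image generators use flat-topped blurred disks with additive Gaussian
  noise — no PSF, photobleaching, uneven illumination or autofluorescence —
  so segmentation difficulty is easier than real microscopy.
- Puncta counts are planted deterministically (rounded expectation), not
  Poisson-sampled, so between-axon variability reflects detection error
  only.
- The Csat estimator assumes a hinge-linear rate-vs-concentration response;
  strongly curved responses above the transition will bias the x-intercept.
- Only straight or polyline axons in 2-D are supported; no 3-D segmentation
  or time-lapse (fusion/FRAP) analysis.
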