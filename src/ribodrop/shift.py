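"""CLIP-target definition and cumulative-shift testing.

Pipeline: annotate binding peaks against gene models (which transcript region
each peak overlaps), select target genes (optionally restricted to peaks in
the mature transcript: 5'UTR, CDS, 3'UTR), restrict targets and non-targets
to a shared log10 base-mean expression window so abundance cannot confound
the comparison, and test whether the targets' signed z-scores are shifted
relative to non-targets with a two-sample Kolmogorov–Smirnov test on the
empirical cumulative distributions.

Coordinates are 0-based half-open throughout this module (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from ribodrop.errors import AnalysisError

#: region labels that belong to the mature transcript
MATURE_REGIONS = frozenset({"five_prime_utr", "cds", "three_prime_utr"})
REGION_LABELS = frozenset({"five_prime_utr", "cds", "three_prime_utr", "intron"})


@dataclass
class ExpressionWindow:
    """Strict log10 base-mean window used for expression matching.

    Genes qualify when ``lo < log10(baseMean) < hi`` (both strict). The
    defaults bracket the mid-abundance range where CLIP targets concentrate.
    """

    lo: float = 2.5
    hi: float = 4.25

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise AnalysisError(f"expression window requires lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, base_mean: np.ndarray) -> np.ndarray:
        base_mean = np.asarray(base_mean, dtype=float)
        with np.errstate(divide="ignore"):
            log_bm = np.where(base_mean > 0, np.log10(np.maximum(base_mean, 1e-300)), -np.inf)
        return (log_bm > self.lo) & (log_bm < self.hi)


@dataclass
class ShiftResult:
    """Outcome of the target-vs-nontarget cumulative shift test."""

    D: float
    p: float
    direction: str  # down | up | none
    n_targets: int
    n_nontargets: int
    median_z_diff: float

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "p": self.p,
            "direction": self.direction,
            "n_targets": self.n_targets,
            "n_nontargets": self.n_nontargets,
            "median_z_diff": self.median_z_diff,
        }


def _strand_compatible(peak_strand: str, model_strand: str) -> bool:
    # require a match only when both records are stranded
    if peak_strand == "." or model_strand == ".":
        return True
    return peak_strand == model_strand


def annotate_peaks(peaks: pd.DataFrame, models: pd.DataFrame) -> pd.DataFrame:
    """Annotate each peak with the gene regions it overlaps.

    Parameters
    ----------
    peaks
        DataFrame with columns ``chrom, start, end, strand`` (0-based
        half-open) and optionally ``gene_id``; the row index identifies peaks.
    models
        DataFrame with columns ``gene, region, chrom, start, end, strand``
        (0-based half-open internal representation; region labels from
        ``five_prime_utr / cds / three_prime_utr / intron``).

    Returns
    -------
    DataFrame
        One row per (peak, gene, region) hit with columns
        ``peak, gene, region``; a peak hits a region when they share ≥ 1 bp
        and their strands are compatible (a ``.`` on either side matches any).
    """
    bad = set(models["region"]) - REGION_LABELS
    if bad:
        raise AnalysisError(f"unknown region labels in gene models: {sorted(bad)}")
    if (peaks["start"] >= peaks["end"]).any():
        row = int(np.argmax((peaks["start"] >= peaks["end"]).to_numpy()))
        raise AnalysisError(f"peak row {row}: start must be < end (0-based half-open)")
    if (models["start"] >= models["end"]).any():
        row = int(np.argmax((models["start"] >= models["end"]).to_numpy()))
        raise AnalysisError(f"gene-model row {row}: start must be < end")

    hits = []
    # sort model intervals per chromosome, sweep each peak over candidates
    by_chrom = {chrom: sub.sort_values("start") for chrom, sub in models.groupby("chrom")}
    for peak_idx, peak in peaks.iterrows():
        sub = by_chrom.get(peak["chrom"])
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        overlap = (starts < peak["end"]) & (ends > peak["start"])
        for _, model in sub[overlap].iterrows():
            if _strand_compatible(str(peak.get("strand", ".")), str(model["strand"])):
                hits.append((peak_idx, model["gene"], model["region"]))
    return pd.DataFrame(hits, columns=["peak", "gene", "region"])


def select_target_genes(hits: pd.DataFrame, mode: str = "mature_only") -> set[str]:
    """Derive the target gene set from annotated peaks.

    ``mature_only`` keeps genes with at least one peak in the mature
    transcript (5'UTR, CDS or 3'UTR), i.e. drops genes bound only in introns;
    ``any`` keeps every gene with any overlapping peak (the right mode when a
    target list already arrives gene-level rather than as peaks).
    """
    if mode not in {"mature_only", "any"}:
        raise AnalysisError(f"unknown target-selection mode {mode!r}")
    if hits.empty:
        return set()
    if mode == "any":
        return set(hits["gene"])
    keep = hits[hits["region"].isin(MATURE_REGIONS)]
    return set(keep["gene"])


def expression_matched_sets(
    de: pd.DataFrame, targets: set[str], window: ExpressionWindow | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split windowed genes into target and non-target z-score vectors.

    Both sets are restricted to genes inside the strict log10 base-mean
    window, so targets and non-targets share the same abundance range;
    non-targets are all windowed genes not in the target set.
    """
    window = window or ExpressionWindow()
    in_window = window.contains(de["baseMean"].to_numpy())
    is_target = de["gene"].isin(targets).to_numpy()
    tz = de.loc[in_window & is_target, "z"].to_numpy(dtype=float)
    nz = de.loc[in_window & ~is_target, "z"].to_numpy(dtype=float)
    if tz.size == 0:
        raise AnalysisError("no target genes inside the expression window")
    if nz.size == 0:
        raise AnalysisError("no non-target genes inside the expression window")
    return tz, nz


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic and asymptotic p-value.

    D is the supremum over the pooled sample points of the absolute ECDF
    difference (ECDFs evaluated at all pooled sorted values, which handles
    ties exactly); the p-value uses the asymptotic Kolmogorov distribution
    with effective size ``n_x * n_y / (n_x + n_y)``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0 or y.size == 0:
        raise AnalysisError("KS test requires non-empty samples")
    pooled = np.concatenate([x, y])
    fx = np.searchsorted(x, pooled, side="right") / x.size
    fy = np.searchsorted(y, pooled, side="right") / y.size
    d = float(np.max(np.abs(fx - fy)))
    en = x.size * y.size / (x.size + y.size)
    p = float(np.clip(special.kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    return d, max(p, np.finfo(float).tiny)


def ecdf_curve(values) -> pd.DataFrame:
    """Step-curve representation of an ECDF (sorted value, cumulative freq)."""
    v = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({"value": v, "ecdf": np.arange(1, v.size + 1) / v.size})


def cumulative_shift(
    de: pd.DataFrame,
    targets: set[str],
    window: ExpressionWindow | None = None,
    alpha: float = 0.05,
) -> tuple[ShiftResult, dict[str, pd.DataFrame]]:
    """Test whether target z-scores are shifted against matched non-targets.

    Returns the :class:`ShiftResult` and the two ECDF step curves (keys
    ``targets`` and ``nontargets``) for plotting. Direction is ``down`` when
    the target ECDF lies left of the non-target ECDF (negative median z
    difference) at p < alpha, ``up`` for a rightward shift, ``none`` when the
    KS test is not significant.
    """
    tz, nz = expression_matched_sets(de, targets, window)
    d, p = ks_two_sample(tz, nz)
    median_diff = float(np.median(tz) - np.median(nz))
    if p < alpha and median_diff < 0:
        direction = "down"
    elif p < alpha and median_diff > 0:
        direction = "up"
    else:
        direction = "none"
    result = ShiftResult(
        D=d, p=p, direction=direction,
        n_targets=int(tz.size), n_nontargets=int(nz.size),
        median_z_diff=median_diff,
    )
    curves = {"targets": ecdf_curve(tz), "nontargets": ecdf_curve(nz)}
    return result, curves
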