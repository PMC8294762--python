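"""Differential translatome statistics.

Implements a self-contained negative-binomial Wald test on raw counts with
median-of-ratios size-factor normalization, Benjamini–Hochberg adjustment,
conversion of two-sided p-values to signed z-scores, and comparison of two
contrasts (shared-gene Pearson correlation of z plus a four-way
condition-specific classification at an adjusted-p cutoff).

The test is intentionally simpler than full DESeq2 machinery (no Cook's
outlier filtering, no fold-change shrinkage): log2 fold changes come straight
from normalized group means with a pseudocount, per-gene dispersions are
method-of-moments estimates, and the standard error is a delta-method
expression under the NB variance function ``mu + alpha * mu**2``. Because a
raw per-gene moment dispersion at typical replicate numbers (4–5 per group)
has only a handful of degrees of freedom, the default estimator moderates each
gene's dispersion toward the across-gene mean with a prior weight of
``dispersion_prior_df`` residual degrees of freedom — the same idea as
empirical-Bayes variance squeezing — which keeps nominal p-values calibrated
under the null. Set ``dispersion_prior_df=0`` for the raw tagwise estimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ribodrop.containers import CONTROL, DE_COLUMNS, MUTANT, CountMatrix
from ribodrop.errors import AnalysisError, NormalizationError

#: p-values below this are clipped before inverse-normal conversion; a
#: two-sided p of 1e-300 maps to |z| ≈ 37, beyond any practical resolution.
P_FLOOR = 1e-300

#: dispersions are floored here so the Wald SE never degenerates to the pure
#: Poisson limit with a negative moment estimate.
DISPERSION_FLOOR = 1e-8


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each gene expressed in every sample, the ratio of its count to the
    gene's geometric mean across samples is formed; a sample's factor is the
    median of those ratios. Requires at least one gene with nonzero counts in
    all samples.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise NormalizationError("no gene has nonzero counts in every sample")
    sub = arr[all_nonzero]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    sf = np.median(ratios, axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=mat.columns, name="size_factor")


def _moment_dispersions(norm: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-group method-of-moments dispersion per gene.

    Returns the raw (possibly negative) estimates and the pooled mean used.
    """
    n_tot = sum(g.sum() for g in groups)
    df = n_tot - len(groups)
    ss = np.zeros(norm.shape[0])
    mean_pool = np.zeros(norm.shape[0])
    for g in groups:
        sub = norm[:, g]
        mu = sub.mean(axis=1)
        ss += ((sub - mu[:, None]) ** 2).sum(axis=1)
        mean_pool += mu * g.sum()
    s2 = ss / df
    mean_pool /= n_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = (s2 - mean_pool) / mean_pool**2
    alpha_raw = np.where(mean_pool > 0, alpha_raw, 0.0)
    return alpha_raw, mean_pool


def nb_wald_test(
    counts: CountMatrix,
    pseudocount: float = 0.5,
    dispersion_prior_df: float = 25.0,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene mutant-vs-control NB Wald test.

    Returns a DataFrame with columns ``gene, baseMean, log2FC, SE, p, padj, z``
    (the canonical differential-expression table). ``log2FC`` is
    ``log2((mu_mut + pc) / (mu_ctl + pc))`` on size-factor-normalized group
    means; ``SE`` is the delta-method standard error under the NB variance
    function; ``p`` is the two-sided normal p of the Wald statistic
    ``log2FC / SE``; ``padj`` is Benjamini–Hochberg; ``z`` the signed
    inverse-normal of ``p``.
    """
    ctl_cols = counts.group_columns(CONTROL)
    mut_cols = counts.group_columns(MUTANT)
    if len(ctl_cols) < 2 or len(mut_cols) < 2:
        raise AnalysisError("need at least 2 samples per group for testing")
    arr = counts.counts.to_numpy(dtype=float)
    if (arr.sum(axis=0) == 0).any():
        raise AnalysisError("a sample library has zero total counts")

    sf = estimate_size_factors(counts) if size_factors is None else size_factors
    norm = arr / sf.to_numpy()[None, :]
    base_mean = norm.mean(axis=1)

    is_ctl = counts.design.to_numpy() == CONTROL
    is_mut = ~is_ctl
    mu_ctl = norm[:, is_ctl].mean(axis=1)
    mu_mut = norm[:, is_mut].mean(axis=1)

    alpha_raw, _ = _moment_dispersions(norm, [is_ctl, is_mut])
    if dispersion_prior_df > 0:
        df_gene = is_ctl.sum() + is_mut.sum() - 2
        alpha_prior = max(float(np.mean(alpha_raw)), DISPERSION_FLOOR)
        alpha = (df_gene * alpha_raw + dispersion_prior_df * alpha_prior) / (
            df_gene + dispersion_prior_df
        )
    else:
        alpha = alpha_raw
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    pc = pseudocount
    log2fc = np.log2((mu_mut + pc) / (mu_ctl + pc))

    ln2sq = np.log(2.0) ** 2
    n_c, n_m = is_ctl.sum(), is_mut.sum()
    var_c = (mu_ctl + alpha * mu_ctl**2) / n_c
    var_m = (mu_mut + alpha * mu_mut**2) / n_m
    se = np.sqrt((var_c / (mu_ctl + pc) ** 2 + var_m / (mu_mut + pc) ** 2) / ln2sq)
    se = np.maximum(se, 1e-12)

    wald = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, P_FLOOR, 1.0)
    padj = bh_adjust(p)
    z = pvalue_to_z(p, log2fc)

    return pd.DataFrame(
        {
            "gene": counts.genes,
            "baseMean": base_mean,
            "log2FC": log2fc,
            "SE": se,
            "p": p,
            "padj": padj,
            "z": z,
        },
        columns=list(DE_COLUMNS),
    ).reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise AnalysisError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pvalue_to_z(p, log2fc):
    """Signed z-score: ``sign(log2fc) * Phi^{-1}(1 - p/2)`` for two-sided p.

    ``p`` below 1e-300 is clipped before conversion. A fold change of exactly
    zero yields z = 0 (its Wald statistic is zero and p = 1).
    """
    p = np.asarray(p, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise AnalysisError("p-values must lie in (0, 1]")
    p = np.clip(p, P_FLOOR, 1.0)
    magnitude = stats.norm.isf(p / 2.0)
    sign = np.sign(log2fc)
    # p = 1 gives magnitude 0 regardless of sign; avoid -0.0
    z = np.where(magnitude == 0.0, 0.0, sign * magnitude)
    return z if z.ndim else float(z)


def compare_contrasts(a: pd.DataFrame, b: pd.DataFrame, alpha: float = 0.1) -> dict:
    """Compare two differential-expression tables on their shared genes.

    Computes the Pearson correlation of signed z-scores and classifies each
    shared gene as ``both`` / ``A_only`` / ``B_only`` / ``neither`` by whether
    its adjusted p is below ``alpha`` in each contrast (significance requires
    strictly ``padj < alpha``; equality counts as non-significant).

    Returns a dict with keys ``genes`` (DataFrame with z_a, z_b, class) ,
    ``pearson_r``, ``pearson_p`` and ``class_counts``.
    """
    merged = a.merge(b, on="gene", suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise AnalysisError("fewer than 3 shared genes: correlation undefined")
    sig_a = merged["padj_a"].to_numpy() < alpha
    sig_b = merged["padj_b"].to_numpy() < alpha
    cls = np.select(
        [sig_a & sig_b, sig_a & ~sig_b, ~sig_a & sig_b],
        ["both", "A_only", "B_only"],
        default="neither",
    )
    r, rp = stats.pearsonr(merged["z_a"], merged["z_b"])
    genes = pd.DataFrame(
        {"gene": merged["gene"], "z_a": merged["z_a"], "z_b": merged["z_b"], "class": cls}
    )
    counts = genes["class"].value_counts().reindex(
        ["both", "A_only", "B_only", "neither"], fill_value=0
    )
    return {
        "genes": genes,
        "pearson_r": float(r),
        "pearson_p": float(rp),
        "class_counts": counts.to_dict(),
    }
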