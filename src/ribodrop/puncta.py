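"""Puncta detection, axonal density and overlap scoring.

Automates a puncta workflow usually done by hand in an image viewer: Otsu
threshold → connected components → records, an inclusive area gate
(0.05–3.00 µm² by default, the conventional proximity-ligation gate), linear
density along a traced axon (puncta per 100 µm), a full/partial/negative
two-channel overlap classification, and control-normalized group summaries
(control mean scaled to 100).

The overlap classes are thresholded on the fraction of a punctum's area
covered by the second channel's mask: ≥ 0.80 is ``full``, ≤ 0.05 is
``negative``, anything between is ``partial``. The thresholds are exposed
because "full" and "partial" are defined pictorially, not numerically, in the
assays this mirrors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, Point
from skimage import measure

from ribodrop.droplets import otsu_mask
from ribodrop.errors import AnalysisError, ConfigError
from ribodrop.de import bh_adjust

DEFAULT_SIZE_GATE = (0.05, 3.00)  # um^2, inclusive
FULL_THRESHOLD = 0.80
NEGATIVE_THRESHOLD = 0.05


def detect_puncta(
    channel: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 0.02,
    min_contrast_sd: float = 3.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Detect puncta by Otsu threshold + 8-connected components.

    Returns a record table (columns ``label, centroid_row, centroid_col,
    area_um2, mean_intensity``) and the label image. Components below
    ``min_area_um2`` are dropped (single-pixel noise). An Otsu threshold
    always splits the histogram, even on a field with no signal, so the
    foreground must additionally clear the background by
    ``min_contrast_sd`` background standard deviations; otherwise the field
    is reported empty.
    """
    mask = otsu_mask(channel)
    channel_arr = np.asarray(channel, dtype=float)
    bg = channel_arr[~mask]
    if bg.size and mask.any():
        contrast = channel_arr[mask].mean() - bg.mean()
        if contrast < min_contrast_sd * bg.std():
            empty = pd.DataFrame(
                columns=["label", "centroid_row", "centroid_col", "area_um2",
                         "mean_intensity"]
            )
            return empty, np.zeros_like(mask, dtype=int)
    labels = measure.label(mask, connectivity=2)
    px_area = pixel_size_um**2
    rows = []
    for prop in measure.regionprops(labels, intensity_image=np.asarray(channel, dtype=float)):
        area = prop.area * px_area
        if area < min_area_um2:
            continue
        rows.append(
            {"label": prop.label, "centroid_row": prop.centroid[0],
             "centroid_col": prop.centroid[1], "area_um2": area,
             "mean_intensity": float(prop.intensity_mean)}
        )
    columns = ["label", "centroid_row", "centroid_col", "area_um2", "mean_intensity"]
    return pd.DataFrame(rows, columns=columns), labels


def size_gate(
    puncta: pd.DataFrame,
    lo_um2: float = DEFAULT_SIZE_GATE[0],
    hi_um2: float = DEFAULT_SIZE_GATE[1],
) -> pd.DataFrame:
    """Keep puncta with ``lo_um2 <= area <= hi_um2`` (inclusive, idempotent)."""
    if lo_um2 > hi_um2:
        raise ConfigError(f"size gate lower bound {lo_um2} exceeds upper bound {hi_um2}")
    keep = (puncta["area_um2"] >= lo_um2) & (puncta["area_um2"] <= hi_um2)
    return puncta[keep].reset_index(drop=True)


def linear_density(
    puncta: pd.DataFrame,
    axon_polyline_um: np.ndarray,
    corridor_um: float = 2.0,
    pixel_size_um: float | None = None,
) -> float:
    """Puncta per 100 µm of axon.

    Counts puncta whose centroid lies within ``corridor_um / 2`` of the axon
    polyline (coordinates in µm, shape (k, 2) as (x, y)); pass
    ``pixel_size_um`` to convert pixel-space centroids. The axon length is
    the polyline arc length.
    """
    poly = np.asarray(axon_polyline_um, dtype=float)
    line = LineString(poly)
    if line.length <= 0:
        raise AnalysisError("axon polyline has zero length")
    if puncta.empty:
        return 0.0
    if pixel_size_um is not None:
        xs = (puncta["centroid_col"].to_numpy() + 0.5) * pixel_size_um
        ys = (puncta["centroid_row"].to_numpy() + 0.5) * pixel_size_um
    else:
        xs = puncta["x_um"].to_numpy()
        ys = puncta["y_um"].to_numpy()
    half = corridor_um / 2.0
    n = sum(line.distance(Point(x, y)) <= half for x, y in zip(xs, ys))
    return 100.0 * n / line.length


def classify_overlap(
    punctum_mask: np.ndarray,
    other_mask: np.ndarray,
    full_threshold: float = FULL_THRESHOLD,
    negative_threshold: float = NEGATIVE_THRESHOLD,
) -> tuple[str, float]:
    """Class and overlap fraction of one punctum against the other channel.

    The overlap fraction is ``|punctum ∩ mask| / |punctum|``.
    """
    punctum_mask = np.asarray(punctum_mask, dtype=bool)
    area = punctum_mask.sum()
    if area == 0:
        raise AnalysisError("punctum has zero area")
    frac = float((punctum_mask & np.asarray(other_mask, dtype=bool)).sum() / area)
    if frac >= full_threshold:
        cls = "full"
    elif frac <= negative_threshold:
        cls = "negative"
    else:
        cls = "partial"
    return cls, frac


def classify_all_overlaps(
    puncta: pd.DataFrame,
    labels: np.ndarray,
    other_mask: np.ndarray,
    full_threshold: float = FULL_THRESHOLD,
    negative_threshold: float = NEGATIVE_THRESHOLD,
) -> pd.DataFrame:
    """Overlap class for every punctum in a detection table."""
    out = puncta.copy()
    classes, fracs = [], []
    for label in out["label"]:
        cls, frac = classify_overlap(
            labels == label, other_mask, full_threshold, negative_threshold
        )
        classes.append(cls)
        fracs.append(frac)
    out["overlap_class"] = classes
    out["overlap_fraction"] = fracs
    return out


def summarize_by_group(
    densities: pd.DataFrame,
    control: str,
) -> pd.DataFrame:
    """Control-normalized group summary of per-axon densities.

    ``densities`` is long-format with columns ``group`` and ``density`` (one
    row per axon). Each density is scaled by ``100 / mean(control)`` so the
    control group averages 100; the summary reports normalized mean ± SEM and
    n per group, plus a Kruskal–Wallis p-value across groups and pairwise
    Mann–Whitney p-values against the control (BH-adjusted) when more than
    one group is present.
    """
    groups = densities.groupby("group", sort=False)["density"]
    if control not in densities["group"].values:
        raise AnalysisError(f"control group {control!r} not present")
    control_mean = float(groups.get_group(control).mean())
    if control_mean == 0:
        raise AnalysisError("control group has zero mean density")
    norm = densities.copy()
    norm["normalized"] = norm["density"] * 100.0 / control_mean
    summary = (
        norm.groupby("group", sort=False)["normalized"]
        .agg(mean="mean", sem=lambda v: v.sem(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )

    samples = [sub.to_numpy() for _, sub in groups]
    if len(samples) > 1 and all(len(s) > 0 for s in samples):
        try:
            summary.attrs["kruskal_p"] = float(stats.kruskal(*samples).pvalue)
        except ValueError:  # all values identical across groups
            summary.attrs["kruskal_p"] = 1.0
        others = [g for g in summary["group"] if g != control]
        pvals = []
        for g in others:
            u = stats.mannwhitneyu(
                groups.get_group(control).to_numpy(), groups.get_group(g).to_numpy(),
                alternative="two-sided",
            )
            pvals.append(float(u.pvalue))
        if pvals:
            adj = bh_adjust(np.asarray(pvals))
            summary.attrs["pairwise_vs_control"] = dict(zip(others, map(float, adj)))
    return summary
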