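"""Condensate partition-enrichment quantification.

Workflow for a two-channel field of phase-separated droplets: subtract a
protein-free blank, segment the scaffold channel with an Otsu threshold,
filter particles by equivalent radius (> 1 µm) and circularity (0.5–1.0),
estimate the dilute-phase background as the mean of droplet-free 5-µm
circular regions of interest, and report per-droplet enrichment ratios
(mean intensity inside the droplet / background mean) for the client channel.

The segmentation channel is configurable: by default the scaffold
(condensate-forming) channel defines masks and the client channel is measured
inside them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

from ribodrop.containers import ImageRaster
from ribodrop.errors import AnalysisError, SegmentationError

DEFAULT_MIN_RADIUS_UM = 1.0
DEFAULT_CIRC_RANGE = (0.5, 1.0)


@dataclass
class EnrichmentResult:
    """Per-droplet enrichment ratios and their arithmetic mean."""

    ratios: np.ndarray
    mean_ratio: float
    background_mean: float
    n_droplets: int

    def to_dict(self) -> dict:
        return {
            "mean_ratio": self.mean_ratio,
            "background_mean": self.background_mean,
            "n_droplets": self.n_droplets,
            "ratios": [float(r) for r in self.ratios],
        }


def subtract_blank(image: ImageRaster, blank: ImageRaster) -> ImageRaster:
    """Subtract a protein-free blank image per pixel, clamping at zero."""
    if set(image.channels) != set(blank.channels):
        raise AnalysisError("blank must provide the same channels as the image")
    out = {}
    for ch, arr in image.channels.items():
        if arr.shape != blank[ch].shape:
            raise AnalysisError(f"channel {ch!r}: blank shape {blank[ch].shape} != {arr.shape}")
        out[ch] = np.clip(arr - blank[ch], 0.0, None)
    return ImageRaster(out, image.pixel_size_um)


def otsu_mask(channel: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels above the Otsu threshold (256-bin histogram)."""
    channel = np.asarray(channel, dtype=float)
    if np.ptp(channel) == 0:
        raise SegmentationError("constant image: Otsu threshold undefined")
    thr = threshold_otsu(channel, nbins=256)
    return channel > thr


def segment_droplets(
    mask: np.ndarray,
    pixel_size_um: float,
    min_radius_um: float = DEFAULT_MIN_RADIUS_UM,
    circ_range: tuple[float, float] = DEFAULT_CIRC_RANGE,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Label connected components and keep droplet-like particles.

    Components are 8-connected. For each, the area, equivalent radius
    ``sqrt(area / pi)`` and circularity ``4 * pi * A / P**2`` (perimeter from
    the 4-direction Crofton estimator; circularity clamped at 1.0 before
    gating) are computed; particles pass with equivalent radius strictly
    greater than ``min_radius_um`` and circularity within ``circ_range``
    (inclusive).

    Returns the record table (columns ``label, area_um2,
    equivalent_radius_um, circularity, centroid_row, centroid_col``) and the
    full label image (unfiltered labels, so rejected particles remain
    addressable).
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    px_area = pixel_size_um**2
    rows = []
    for prop in measure.regionprops(labels):
        area_um2 = prop.area * px_area
        radius_um = float(np.sqrt(area_um2 / np.pi))
        perimeter_um = prop.perimeter_crofton * pixel_size_um
        if perimeter_um <= 0:
            continue
        circ = min(4.0 * np.pi * area_um2 / perimeter_um**2, 1.0)
        if radius_um > min_radius_um and circ_range[0] <= circ <= circ_range[1]:
            rows.append(
                {
                    "label": prop.label,
                    "area_um2": area_um2,
                    "equivalent_radius_um": radius_um,
                    "circularity": circ,
                    "centroid_row": prop.centroid[0],
                    "centroid_col": prop.centroid[1],
                }
            )
    columns = ["label", "area_um2", "equivalent_radius_um", "circularity",
               "centroid_row", "centroid_col"]
    return pd.DataFrame(rows, columns=columns), labels


def background_mean(
    channel: np.ndarray,
    droplet_mask: np.ndarray,
    pixel_size_um: float,
    roi_diameter_um: float = 5.0,
    n_rois: int = 5,
    seed: int = 0,
    max_attempts: int = 10000,
) -> float:
    """Dilute-phase background from random droplet-free circular ROIs.

    Circular ROIs of the given diameter are placed at seeded random positions
    fully inside the image with zero overlap with the droplet mask; the
    returned background is the average of the ROI means (several ROIs reduce
    the variance of a single manual pick).
    """
    channel = np.asarray(channel, dtype=float)
    droplet_mask = np.asarray(droplet_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    r_px = (roi_diameter_um / 2.0) / pixel_size_um
    ny, nx = channel.shape
    if 2 * r_px >= min(ny, nx):
        raise SegmentationError("ROI diameter exceeds the image size")

    yy, xx = np.mgrid[0:ny, 0:nx]
    means = []
    attempts = 0
    while len(means) < n_rois:
        if attempts >= max_attempts:
            raise SegmentationError(
                f"no droplet-free {roi_diameter_um}-um ROI found in {max_attempts} attempts"
            )
        attempts += 1
        cy = rng.uniform(r_px, ny - r_px)
        cx = rng.uniform(r_px, nx - r_px)
        roi = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        if not roi.any() or (roi & droplet_mask).any():
            continue
        means.append(float(channel[roi].mean()))
    return float(np.mean(means))


def enrichment_ratios(
    image: ImageRaster,
    droplets: pd.DataFrame,
    labels: np.ndarray,
    channel: str,
    background: float,
) -> EnrichmentResult:
    """Per-droplet enrichment: mean client intensity inside / background."""
    if background <= 0:
        raise AnalysisError("background mean must be positive")
    arr = image[channel]
    ratios = []
    for label in droplets["label"]:
        inside = arr[labels == label]
        ratios.append(float(inside.mean()) / background)
    ratios = np.asarray(ratios, dtype=float)
    mean_ratio = float(ratios.mean()) if ratios.size else float("nan")
    return EnrichmentResult(
        ratios=ratios,
        mean_ratio=mean_ratio,
        background_mean=float(background),
        n_droplets=int(ratios.size),
    )


def quantify_partition(
    image: ImageRaster,
    blank: ImageRaster | None = None,
    scaffold: str = "scaffold",
    client: str = "client",
    min_radius_um: float = DEFAULT_MIN_RADIUS_UM,
    circ_range: tuple[float, float] = DEFAULT_CIRC_RANGE,
    roi_diameter_um: float = 5.0,
    n_rois: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, EnrichmentResult]:
    """Full partition analysis of one field.

    Blank-subtracts (when a blank is given), builds the Otsu mask on the
    scaffold channel, filters particles, estimates the client-channel
    background outside droplets and returns the droplet table (with
    per-channel mean intensities) plus the client-channel enrichment result.
    """
    if blank is not None:
        image = subtract_blank(image, blank)
    mask = otsu_mask(image[scaffold])
    droplets, labels = segment_droplets(mask, image.pixel_size_um, min_radius_um, circ_range)
    for ch, arr in image.channels.items():
        droplets[f"mean_{ch}"] = [
            float(arr[labels == label].mean()) for label in droplets["label"]
        ]
    bg = background_mean(
        image[client], mask, image.pixel_size_um, roi_diameter_um, n_rois, seed
    )
    result = enrichment_ratios(image, droplets, labels, client, bg)
    droplets[f"ratio_{client}"] = result.ratios
    return droplets, result
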