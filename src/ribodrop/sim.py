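"""Synthetic-data generators with recorded ground truth.

Every generator is a pure function of its configuration and seed
(bit-reproducible), and returns a ground-truth table sufficient to score the
downstream analysis without re-deriving truth from the generated pixels or
counts.

Generators
----------
simulate_counts
    Negative-binomial count matrices emulating a ribosome-affinity (RiboTag)
    translatome design: two genotype groups, per-sample size factors, and a
    planted log2 fold change on a flagged subset of "target" genes.
simulate_droplet_field
    Two-channel images of phase-separated droplets on a dilute background with
    known inside/outside intensities per channel, i.e. known partition ratios.
simulate_kinetics
    Saturating-exponential turbidity (OD600) or luminescence traces whose
    early-phase slope equals a configured initial rate.
simulate_axon_image
    Two-channel axon images with puncta of controlled linear density and a
    planted full/partial/negative channel-overlap composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ribodrop._utils import require
from ribodrop.containers import CONTROL, MUTANT, CountMatrix, ImageRaster, KineticSeries
from ribodrop.errors import ConfigError, GenerationError

# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class SimCountConfig:
    """Configuration of the negative-binomial translatome simulator.

    The negative binomial is parameterized by mean ``mu`` and dispersion
    ``alpha`` with variance ``mu + alpha * mu**2``. Per-gene baseline means
    are log10-normal; target genes get expected mutant/control mean ratio
    ``2**target_log2fc``. Per-sample size factors are drawn uniformly from
    ``size_factor_range`` and rescaled to geometric mean 1.

    Defaults mirror the translatome study design this emulates: 5 mutant vs
    5 littermate-control libraries, ~2000 genes spanning the tens-to-tens-of-
    thousands count range, moderate biological dispersion, and depletion of a
    20% target-gene subset by one log2 unit.
    """

    n_genes: int = 2000
    n_per_group: int | tuple[int, int] = (5, 5)  # (control, mutant)
    mean_log10_basemean: float = 3.0
    sd_log10_basemean: float = 0.8
    dispersion: float = 0.05
    target_fraction: float = 0.2
    target_log2fc: float = -1.0
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.n_genes > 0, "n_genes", "must be a positive integer")
        n = self.n_per_group
        if isinstance(n, int):
            n = (n, n)
        self.n_per_group = (int(n[0]), int(n[1]))
        require(min(self.n_per_group) > 0, "n_per_group", "must be positive per group")
        require(self.sd_log10_basemean > 0, "sd_log10_basemean", "must be positive")
        require(self.dispersion > 0, "dispersion", "must be positive")
        require(0.0 <= self.target_fraction <= 1.0, "target_fraction", "must lie in [0, 1]")
        lo, hi = self.size_factor_range
        require(0 < lo <= hi, "size_factor_range", "must be an increasing pair of positive reals")

    @property
    def n_targets(self) -> int:
        return int(round(self.target_fraction * self.n_genes))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma–Poisson draw of NB(mean, alpha) counts; exact for all alpha > 0."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean)
    return rng.poisson(lam)


def simulate_counts(cfg: SimCountConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a two-group translatome count matrix.

    Returns
    -------
    (CountMatrix, DataFrame)
        The count matrix (genes × samples, raw integer counts) and a
        ground-truth table with columns ``gene``, ``is_target``,
        ``true_log2fc``, ``mu_control`` plus per-sample true size factors in
        ``DataFrame.attrs["size_factors"]``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ctl, n_mut = cfg.n_per_group
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    samples = [f"ctl{j + 1}" for j in range(n_ctl)] + [f"mut{j + 1}" for j in range(n_mut)]
    design = pd.Series([CONTROL] * n_ctl + [MUTANT] * n_mut, index=samples, name="group")

    mu_ctl = 10.0 ** rng.normal(cfg.mean_log10_basemean, cfg.sd_log10_basemean, cfg.n_genes)
    is_target = np.zeros(cfg.n_genes, dtype=bool)
    is_target[rng.choice(cfg.n_genes, size=cfg.n_targets, replace=False)] = True
    true_log2fc = np.where(is_target, cfg.target_log2fc, 0.0)
    mu_mut = mu_ctl * 2.0**true_log2fc

    sf = rng.uniform(*cfg.size_factor_range, size=n_ctl + n_mut)
    sf = sf / np.exp(np.mean(np.log(sf)))

    mu = np.column_stack([mu_ctl] * n_ctl + [mu_mut] * n_mut) * sf[None, :]
    counts = _nb_draw(rng, mu, cfg.dispersion)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), design)
    truth = pd.DataFrame(
        {"gene": genes, "is_target": is_target, "true_log2fc": true_log2fc, "mu_control": mu_ctl}
    )
    truth.attrs["size_factors"] = pd.Series(sf, index=samples, name="size_factor")
    return cm, truth


# ---------------------------------------------------------------------------
# Droplet fields
# ---------------------------------------------------------------------------


@dataclass
class SimDropletConfig:
    """Configuration of the two-channel droplet-field simulator.

    Droplets are non-overlapping disks, fully inside the field, painted at
    ``channel_inside_mean`` on a ``channel_outside_mean`` background, then
    optionally Gaussian-blurred and corrupted with additive Gaussian noise.
    The planted per-channel partition ratio is ``inside / outside``.

    Default intensities put the scaffold (condensate-forming) channel at high
    contrast for segmentation and the client channel at a partition ratio of
    3.5, on the scale of measured condensate enrichments.
    """

    field_size_um: tuple[float, float] = (100.0, 100.0)
    pixel_size_um: float = 0.2
    n_droplets: int = 25
    radius_um_range: tuple[float, float] = (1.5, 4.0)
    channel_inside_mean: dict[str, float] = field(
        default_factory=lambda: {"scaffold": 400.0, "client": 350.0}
    )
    channel_outside_mean: dict[str, float] = field(
        default_factory=lambda: {"scaffold": 50.0, "client": 100.0}
    )
    noise_sd: float = 5.0
    blur_sigma_px: float = 1.0
    min_gap_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.pixel_size_um > 0, "pixel_size_um", "must be positive")
        require(self.n_droplets >= 0, "n_droplets", "must be >= 0")
        lo, hi = self.radius_um_range
        require(0 < lo <= hi, "radius_um_range", "must be an increasing positive pair")
        require(
            set(self.channel_inside_mean) == set(self.channel_outside_mean),
            "channel_outside_mean",
            "must name the same channels as channel_inside_mean",
        )
        for ch, v in self.channel_inside_mean.items():
            require(v > 0, f"channel_inside_mean[{ch}]", "must be positive")
        for ch, v in self.channel_outside_mean.items():
            require(v > 0, f"channel_outside_mean[{ch}]", "must be positive")
        require(self.noise_sd >= 0, "noise_sd", "must be non-negative")
        require(self.blur_sigma_px >= 0, "blur_sigma_px", "must be non-negative")


def _place_disks(
    rng: np.random.Generator,
    n: int,
    radii: np.ndarray,
    bounds: tuple[float, float],
    gap: float,
    max_attempts: int,
) -> np.ndarray:
    """Rejection-sample ``n`` non-overlapping disk centers inside the field."""
    width, height = bounds
    centers: list[tuple[float, float]] = []
    attempts = 0
    i = 0
    while i < n:
        if attempts >= max_attempts:
            raise GenerationError(
                f"could not place {n} non-overlapping droplets in {max_attempts} attempts; "
                "request fewer or smaller droplets"
            )
        attempts += 1
        r = radii[i]
        x = rng.uniform(r, width - r)
        y = rng.uniform(r, height - r)
        ok = all(
            np.hypot(x - cx, y - cy) > r + radii[j] + gap for j, (cx, cy) in enumerate(centers)
        )
        if ok:
            centers.append((x, y))
            i += 1
    return np.asarray(centers).reshape(n, 2)


def simulate_droplet_field(cfg: SimDropletConfig) -> tuple[ImageRaster, pd.DataFrame]:
    """Simulate a droplet field; returns the raster and the planted table.

    The planted table has one row per droplet with columns ``droplet``,
    ``x_um``, ``y_um``, ``radius_um`` and ``true_ratio_<channel>`` for each
    channel.
    """
    rng = np.random.default_rng(cfg.seed)
    width_um, height_um = cfg.field_size_um
    ny = int(round(height_um / cfg.pixel_size_um))
    nx = int(round(width_um / cfg.pixel_size_um))

    radii = rng.uniform(*cfg.radius_um_range, size=cfg.n_droplets)
    if cfg.n_droplets > 0:
        r_max = radii.max()
        require(
            2 * r_max < min(width_um, height_um),
            "radius_um_range",
            "droplets must fit inside the field",
        )
    centers = _place_disks(
        rng, cfg.n_droplets, radii, (width_um, height_um), cfg.min_gap_um, 10 * max(cfg.n_droplets, 1)
    )

    yy, xx = np.mgrid[0:ny, 0:nx]
    # pixel centers in micrometres
    xum = (xx + 0.5) * cfg.pixel_size_um
    yum = (yy + 0.5) * cfg.pixel_size_um
    disk_mask = np.zeros((ny, nx), dtype=bool)
    for (cx, cy), r in zip(centers, radii):
        disk_mask |= (xum - cx) ** 2 + (yum - cy) ** 2 <= r**2

    channels: dict[str, np.ndarray] = {}
    for ch in cfg.channel_inside_mean:
        inside, outside = cfg.channel_inside_mean[ch], cfg.channel_outside_mean[ch]
        img = np.full((ny, nx), outside, dtype=float)
        img[disk_mask] = inside
        if cfg.blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, cfg.blur_sigma_px)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
        channels[ch] = np.clip(img, 0.0, None)

    rows = []
    for i, ((cx, cy), r) in enumerate(zip(centers, radii)):
        row = {"droplet": i, "x_um": cx, "y_um": cy, "radius_um": r}
        for ch in cfg.channel_inside_mean:
            row[f"true_ratio_{ch}"] = cfg.channel_inside_mean[ch] / cfg.channel_outside_mean[ch]
        rows.append(row)
    planted = pd.DataFrame(
        rows,
        columns=["droplet", "x_um", "y_um", "radius_um"]
        + [f"true_ratio_{ch}" for ch in cfg.channel_inside_mean],
    )
    return ImageRaster(channels, cfg.pixel_size_um), planted


# ---------------------------------------------------------------------------
# Kinetic traces
# ---------------------------------------------------------------------------


@dataclass
class SimKineticConfig:
    """Configuration of the saturating-exponential kinetic-trace simulator.

    The noiseless trace is ``plateau * (1 - exp(-initial_rate * t / plateau))``
    so the slope at t = 0 equals ``initial_rate`` and the signal saturates
    toward ``plateau``. Noise is additive Gaussian truncated at ±5 standard
    deviations (plate-reader noise has no heavy tail at this scale), so the
    signal never exceeds ``plateau + 5 * noise_sd``.

    Turbidity defaults follow the plate-reader protocol of 35-s sampling for
    20 min; luminescence defaults follow end-point reads every 10 min up to
    50 min (the first read after a 10-min incubation, so t starts at 10 min).
    """

    assay: str = "turbidity"
    initial_rate: float | None = None
    plateau: float | None = None
    sampling_interval_min: float | None = None
    duration_min: float | None = None
    noise_sd: float | None = None
    seed: int = 0

    _DEFAULTS = {
        "turbidity": dict(
            initial_rate=0.005, plateau=0.5, sampling_interval_min=35.0 / 60.0,
            duration_min=20.0, noise_sd=0.002,
        ),
        "luminescence": dict(
            initial_rate=1000.0, plateau=1.0e5, sampling_interval_min=10.0,
            duration_min=50.0, noise_sd=500.0,
        ),
    }

    def __post_init__(self) -> None:
        require(self.assay in self._DEFAULTS, "assay", "must be 'turbidity' or 'luminescence'")
        for name, default in self._DEFAULTS[self.assay].items():
            if getattr(self, name) is None:
                setattr(self, name, default)
        require(self.plateau > 0, "plateau", "must be positive")
        require(self.sampling_interval_min > 0, "sampling_interval_min", "must be positive")
        require(self.noise_sd >= 0, "noise_sd", "must be non-negative")
        require(
            self.duration_min >= self.sampling_interval_min,
            "duration_min",
            "must cover at least one sampling interval",
        )
        n_pts = len(self.time_grid())
        require(n_pts >= 2, "duration_min", "needs at least 2 time points in the series")

    def time_grid(self) -> np.ndarray:
        dt = self.sampling_interval_min
        if self.assay == "turbidity":
            start = 0.0
        else:  # luminescence reads begin after the first incubation interval
            start = dt
        return np.arange(start, self.duration_min + 1e-9, dt)


def simulate_kinetics(cfg: SimKineticConfig, condition: str = "sample") -> KineticSeries:
    """Simulate one kinetic trace (turbidity or luminescence)."""
    rng = np.random.default_rng(cfg.seed)
    t = cfg.time_grid()
    clean = cfg.plateau * -np.expm1(-cfg.initial_rate * t / cfg.plateau)
    if cfg.noise_sd > 0:
        noise = np.clip(rng.normal(0.0, cfg.noise_sd, t.shape), -5 * cfg.noise_sd, 5 * cfg.noise_sd)
    else:
        noise = 0.0
    return KineticSeries(
        time_min=t,
        signal=clean + noise,
        condition=condition,
        assay=cfg.assay,
        meta={"initial_rate": cfg.initial_rate, "plateau": cfg.plateau, "seed": cfg.seed},
    )


# ---------------------------------------------------------------------------
# Axon images
# ---------------------------------------------------------------------------


@dataclass
class SimAxonConfig:
    """Configuration of the two-channel axon puncta simulator.

    The axon is a straight horizontal corridor of width ``corridor_width_um``
    (linear density is per unit length, so the geometry is irrelevant to the
    statistic). Channel ``ch1`` plays the role of the scored puncta (e.g.
    FMRP granules); channel ``ch2`` the co-staining protein whose mask defines
    overlap. Each ch1 punctum is planted with a known overlap class:

    ``full``
        a ch2 partner disk concentric with and slightly larger than the
        punctum (overlap fraction 1);
    ``partial``
        an equal-radius ch2 partner offset by one radius (overlap fraction
        ≈ 0.39 for equal disks);
    ``negative``
        no ch2 signal touching the punctum.

    Remaining ch2 puncta (beyond the partners) are placed away from every ch1
    punctum so planted classes stay exact.
    """

    axon_length_um: float = 500.0
    corridor_width_um: float = 2.0
    puncta_per_100um: dict[str, float] = field(
        default_factory=lambda: {"ch1": 10.0, "ch2": 15.0}
    )
    punctum_area_um2_range: tuple[float, float] = (0.15, 0.45)
    overlap_full_frac: float = 0.2
    overlap_partial_frac: float = 0.4
    pixel_size_um: float = 0.1
    background: float = 20.0
    amplitude: float = 200.0
    noise_sd: float = 4.0
    blur_sigma_px: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.axon_length_um > 0, "axon_length_um", "must be positive")
        require(self.corridor_width_um > 0, "corridor_width_um", "must be positive")
        require(set(self.puncta_per_100um) == {"ch1", "ch2"}, "puncta_per_100um",
                "must give densities for channels 'ch1' and 'ch2'")
        require(all(v >= 0 for v in self.puncta_per_100um.values()),
                "puncta_per_100um", "densities must be non-negative")
        lo, hi = self.punctum_area_um2_range
        require(0 < lo <= hi, "punctum_area_um2_range", "must be an increasing positive pair")
        r_max = float(np.sqrt(hi / np.pi))
        require(2 * r_max <= self.corridor_width_um, "punctum_area_um2_range",
                "punctum diameter exceeds the axon corridor width")
        require(0 <= self.overlap_full_frac <= 1, "overlap_full_frac", "must lie in [0, 1]")
        require(0 <= self.overlap_partial_frac <= 1, "overlap_partial_frac", "must lie in [0, 1]")
        require(self.overlap_full_frac + self.overlap_partial_frac <= 1,
                "overlap_partial_frac", "full + partial fractions must not exceed 1")
        require(self.pixel_size_um > 0, "pixel_size_um", "must be positive")
        require(self.noise_sd >= 0, "noise_sd", "must be non-negative")

    def planted_count(self, channel: str) -> int:
        return int(round(self.puncta_per_100um[channel] * self.axon_length_um / 100.0))


def _sample_separated_x(
    rng: np.random.Generator, n: int, length: float, min_sep: float, max_attempts: int = 100000
) -> np.ndarray:
    """Sample ``n`` x-positions in (0, length) pairwise at least ``min_sep`` apart."""
    xs: list[float] = []
    attempts = 0
    while len(xs) < n:
        if attempts >= max_attempts:
            raise GenerationError(
                f"could not place {n} puncta with separation {min_sep} on length {length}"
            )
        attempts += 1
        x = rng.uniform(min_sep, length - min_sep)
        if all(abs(x - other) > min_sep for other in xs):
            xs.append(x)
    return np.asarray(xs)


def simulate_axon_image(cfg: SimAxonConfig) -> tuple[ImageRaster, pd.DataFrame]:
    """Simulate a two-channel axon image with planted puncta.

    Returns the raster and a planted table with columns ``channel``, ``x_um``,
    ``y_um``, ``radius_um``, ``area_um2`` and, for ch1 puncta, ``overlap_class``.
    """
    rng = np.random.default_rng(cfg.seed)
    n1 = cfg.planted_count("ch1")
    n2 = cfg.planted_count("ch2")
    n_full = int(round(cfg.overlap_full_frac * n1))
    n_partial = int(round(cfg.overlap_partial_frac * n1))
    if n2 < n_full + n_partial:
        raise ConfigError(
            "puncta_per_100um[ch2]: too few ch2 puncta to host the requested "
            f"overlap partners ({n2} < {n_full + n_partial})"
        )

    margin_um = 2.0  # dark margin above/below the corridor
    height_um = cfg.corridor_width_um + 2 * margin_um
    ny = int(round(height_um / cfg.pixel_size_um))
    nx = int(round(cfg.axon_length_um / cfg.pixel_size_um))

    lo_a, hi_a = cfg.punctum_area_um2_range
    r1 = np.sqrt(rng.uniform(lo_a, hi_a, n1) / np.pi)
    # ch1 centers: separated so detection cannot merge neighbours and partner
    # disks cannot graze an unrelated punctum
    min_sep = 2 * np.sqrt(hi_a / np.pi) * 2.5
    x1 = _sample_separated_x(rng, n1, cfg.axon_length_um, min_sep)
    y_half = cfg.corridor_width_um / 2.0
    y1 = margin_um + y_half + rng.uniform(-1, 1, n1) * np.maximum(y_half - r1, 0.0)

    classes = np.array(
        ["full"] * n_full + ["partial"] * n_partial + ["negative"] * (n1 - n_full - n_partial)
    )
    rng.shuffle(classes)

    rows = []
    disks1 = []
    disks2 = []
    for i in range(n1):
        rows.append(
            {"channel": "ch1", "x_um": x1[i], "y_um": y1[i], "radius_um": r1[i],
             "area_um2": np.pi * r1[i] ** 2, "overlap_class": classes[i]}
        )
        disks1.append((x1[i], y1[i], r1[i]))
        if classes[i] == "full":
            disks2.append((x1[i], y1[i], 1.2 * r1[i]))
            rows.append({"channel": "ch2", "x_um": x1[i], "y_um": y1[i],
                         "radius_um": 1.2 * r1[i], "area_um2": np.pi * (1.2 * r1[i]) ** 2,
                         "overlap_class": ""})
        elif classes[i] == "partial":
            dx = r1[i] * rng.choice([-1.0, 1.0])
            disks2.append((x1[i] + dx, y1[i], r1[i]))
            rows.append({"channel": "ch2", "x_um": x1[i] + dx, "y_um": y1[i],
                         "radius_um": r1[i], "area_um2": np.pi * r1[i] ** 2,
                         "overlap_class": ""})

    # independent ch2 puncta, kept clear of every ch1 punctum
    n_extra = n2 - n_full - n_partial
    r2 = np.sqrt(rng.uniform(lo_a, hi_a, n_extra) / np.pi)
    placed = 0
    attempts = 0
    while placed < n_extra:
        if attempts > 100000:
            raise GenerationError("could not place independent ch2 puncta clear of ch1 puncta")
        attempts += 1
        r = r2[placed]
        x = rng.uniform(r, cfg.axon_length_um - r)
        y = margin_um + y_half + rng.uniform(-1, 1) * max(y_half - r, 0.0)
        clear_of_ch1 = all(np.hypot(x - cx, y - cy) > r + cr + 3 * cfg.pixel_size_um
                           for cx, cy, cr in disks1)
        clear_of_ch2 = all(np.hypot(x - cx, y - cy) > r + cr + 2 * cfg.pixel_size_um
                           for cx, cy, cr in disks2)
        if clear_of_ch1 and clear_of_ch2:
            disks2.append((x, y, r))
            rows.append({"channel": "ch2", "x_um": x, "y_um": y, "radius_um": r,
                         "area_um2": np.pi * r**2, "overlap_class": ""})
            placed += 1

    yy, xx = np.mgrid[0:ny, 0:nx]
    xum = (xx + 0.5) * cfg.pixel_size_um
    yum = (yy + 0.5) * cfg.pixel_size_um

    def render(disks: list[tuple[float, float, float]]) -> np.ndarray:
        img = np.full((ny, nx), cfg.background, dtype=float)
        for cx, cy, r in disks:
            mask = (xum - cx) ** 2 + (yum - cy) ** 2 <= r**2
            img[mask] = cfg.background + cfg.amplitude
        if cfg.blur_sigma_px > 0:
            img = ndimage.gaussian_filter(img, cfg.blur_sigma_px)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
        return np.clip(img, 0.0, None)

    raster = ImageRaster({"ch1": render(disks1), "ch2": render(disks2)}, cfg.pixel_size_um)
    planted = pd.DataFrame(
        rows, columns=["channel", "x_um", "y_um", "radius_um", "area_um2", "overlap_class"]
    )
    return raster, planted
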