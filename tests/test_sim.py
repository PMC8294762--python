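"""Generator correctness: determinism, planted effects, marginal laws."""

import numpy as np
import pandas as pd
import pytest

from ribodrop import sim
from ribodrop.errors import ConfigError, GenerationError


class TestSimulateCounts:
    def test_same_seed_bit_identical(self):
        a, ta = sim.simulate_counts(sim.SimCountConfig(n_genes=100, seed=7))
        b, tb = sim.simulate_counts(sim.SimCountConfig(n_genes=100, seed=7))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(ta, tb)

    def test_low_dispersion_means_match_planted(self):
        # law of large numbers: near-Poisson counts at 200/group, unit size
        # factors -> per-gene sample mean within 1% of the planted mean
        cfg = sim.SimCountConfig(
            n_genes=500, n_per_group=200, mean_log10_basemean=4.0,
            sd_log10_basemean=0.2, dispersion=1e-8, target_log2fc=0.0,
            size_factor_range=(1.0, 1.0), seed=3,
        )
        cm, truth = sim.simulate_counts(cfg)
        sample_mean = cm.counts.to_numpy().mean(axis=1)
        rel = np.abs(sample_mean - truth["mu_control"]) / truth["mu_control"]
        assert rel.max() < 0.01

    def test_planted_fold_change_recovered(self):
        cfg = sim.SimCountConfig(
            n_genes=2000, target_log2fc=-0.5, size_factor_range=(1.0, 1.0), seed=5
        )
        cm, truth = sim.simulate_counts(cfg)
        tgt = truth["is_target"].to_numpy()
        ctl_cols = cm.group_columns("control")
        mut_cols = cm.group_columns("mutant")
        ratio = (
            cm.counts.loc[tgt, mut_cols].to_numpy().mean()
            / cm.counts.loc[tgt, ctl_cols].to_numpy().mean()
        )
        assert ratio == pytest.approx(2**-0.5, rel=0.05)

    def test_target_count_and_truth_columns(self):
        cfg = sim.SimCountConfig(n_genes=1000, target_fraction=0.25, seed=0)
        _, truth = sim.simulate_counts(cfg)
        assert truth["is_target"].sum() == 250
        assert (truth.loc[truth["is_target"], "true_log2fc"] == cfg.target_log2fc).all()
        assert (truth.loc[~truth["is_target"], "true_log2fc"] == 0).all()

    def test_moment_dispersion_recovered(self):
        # marginal check: pooled method-of-moments over many genes recovers
        # the generative dispersion
        cfg = sim.SimCountConfig(
            n_genes=10000, dispersion=0.2, target_log2fc=0.0,
            size_factor_range=(1.0, 1.0), seed=11,
        )
        cm, _ = sim.simulate_counts(cfg)
        arr = cm.counts.to_numpy(dtype=float)
        mu = arr.mean(axis=1)
        s2 = arr.var(axis=1, ddof=1)
        keep = mu > 0
        alpha_hat = np.mean((s2[keep] - mu[keep]) / mu[keep] ** 2)
        assert alpha_hat == pytest.approx(0.2, abs=0.05)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="dispersion"):
            sim.SimCountConfig(dispersion=-1)
        with pytest.raises(ConfigError, match="target_fraction"):
            sim.SimCountConfig(target_fraction=1.5)


class TestSimulateDropletField:
    def test_noiseless_disks_exact(self):
        cfg = sim.SimDropletConfig(n_droplets=5, noise_sd=0.0, blur_sigma_px=0.0, seed=2)
        raster, planted = sim.simulate_droplet_field(cfg)
        assert len(planted) == 5
        px = cfg.pixel_size_um
        yy, xx = np.mgrid[0 : raster.shape[0], 0 : raster.shape[1]]
        for _, row in planted.iterrows():
            disk = ((xx + 0.5) * px - row.x_um) ** 2 + ((yy + 0.5) * px - row.y_um) ** 2 <= row.radius_um**2
            assert raster["scaffold"][disk].mean() == 400.0
            assert raster["client"][disk].mean() == 350.0

    def test_zero_droplets_uniform(self):
        cfg = sim.SimDropletConfig(n_droplets=0, noise_sd=0.0, blur_sigma_px=0.0)
        raster, planted = sim.simulate_droplet_field(cfg)
        assert planted.empty
        assert (raster["scaffold"] == 50.0).all()

    def test_seed_determinism(self):
        a, _ = sim.simulate_droplet_field(sim.SimDropletConfig(seed=9))
        b, _ = sim.simulate_droplet_field(sim.SimDropletConfig(seed=9))
        np.testing.assert_array_equal(a["client"], b["client"])

    def test_droplets_disjoint_and_inside(self):
        cfg = sim.SimDropletConfig(n_droplets=25, seed=4)
        _, planted = sim.simulate_droplet_field(cfg)
        w, h = cfg.field_size_um
        assert ((planted.x_um - planted.radius_um) >= 0).all()
        assert ((planted.x_um + planted.radius_um) <= w).all()
        assert ((planted.y_um + planted.radius_um) <= h).all()
        xy = planted[["x_um", "y_um"]].to_numpy()
        r = planted["radius_um"].to_numpy()
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
        sep = r[:, None] + r[None, :]
        off_diag = ~np.eye(len(r), dtype=bool)
        assert (d[off_diag] > sep[off_diag]).all()

    def test_impossible_packing_raises(self):
        cfg = sim.SimDropletConfig(
            field_size_um=(30.0, 30.0), n_droplets=40, radius_um_range=(4.0, 5.0), seed=0
        )
        with pytest.raises(GenerationError, match="fewer or smaller"):
            sim.simulate_droplet_field(cfg)


class TestSimulateKinetics:
    def test_linear_regime_slope_equals_rate(self):
        cfg = sim.SimKineticConfig(
            assay="turbidity", initial_rate=0.01, plateau=1e6, noise_sd=0.0
        )
        series = sim.simulate_kinetics(cfg)
        keep = series.time_min <= 5.0
        slope = np.polyfit(series.time_min[keep], series.signal[keep], 1)[0]
        assert slope == pytest.approx(0.01, rel=1e-6)

    def test_luminescence_default_grid(self):
        series = sim.simulate_kinetics(sim.SimKineticConfig(assay="luminescence"))
        np.testing.assert_allclose(series.time_min, [10, 20, 30, 40, 50])

    def test_turbidity_default_grid(self):
        series = sim.simulate_kinetics(sim.SimKineticConfig(assay="turbidity"))
        assert series.time_min[0] == 0.0
        assert series.time_min[-1] <= 20.0
        assert np.allclose(np.diff(series.time_min), 35.0 / 60.0)

    def test_signal_bounded_by_plateau_plus_noise(self):
        bound_ok = True
        for seed in range(1000):
            cfg = sim.SimKineticConfig(assay="turbidity", seed=seed)
            s = sim.simulate_kinetics(cfg)
            bound_ok &= bool((s.signal <= cfg.plateau + 5 * cfg.noise_sd).all())
        assert bound_ok

    def test_duration_shorter_than_interval_rejected(self):
        with pytest.raises(ConfigError, match="duration_min"):
            sim.SimKineticConfig(assay="luminescence", duration_min=5.0)


class TestSimulateAxonImage:
    def test_exact_planted_count(self):
        cfg = sim.SimAxonConfig(
            axon_length_um=500.0, puncta_per_100um={"ch1": 10.0, "ch2": 15.0}, seed=1
        )
        _, planted = sim.simulate_axon_image(cfg)
        assert (planted.channel == "ch1").sum() == 50
        assert (planted.channel == "ch2").sum() == 75

    def test_full_overlap_everywhere(self):
        cfg = sim.SimAxonConfig(
            axon_length_um=200.0, overlap_full_frac=1.0, overlap_partial_frac=0.0,
            puncta_per_100um={"ch1": 8.0, "ch2": 16.0}, noise_sd=0.0,
            blur_sigma_px=0.0, seed=2,
        )
        raster, planted = sim.simulate_axon_image(cfg)
        ch1 = planted[planted.channel == "ch1"]
        assert (ch1.overlap_class == "full").all()
        # every bright ch1 pixel is also bright in ch2 (partner disks are larger)
        m1 = raster["ch1"] > cfg.background + cfg.amplitude / 2
        m2 = raster["ch2"] > cfg.background + cfg.amplitude / 2
        assert (m2 | ~m1).all()

    def test_seed_determinism(self):
        a, pa = sim.simulate_axon_image(sim.SimAxonConfig(axon_length_um=100.0, seed=5))
        b, pb = sim.simulate_axon_image(sim.SimAxonConfig(axon_length_um=100.0, seed=5))
        np.testing.assert_array_equal(a["ch1"], b["ch1"])
        pd.testing.assert_frame_equal(pa, pb)

    def test_centroids_on_corridor(self):
        cfg = sim.SimAxonConfig(axon_length_um=300.0, seed=8)
        _, planted = sim.simulate_axon_image(cfg)
        mid = 2.0 + cfg.corridor_width_um / 2.0
        assert (np.abs(planted.y_um - mid) <= cfg.corridor_width_um / 2.0).all()

    def test_oversized_punctum_rejected(self):
        with pytest.raises(ConfigError, match="corridor"):
            sim.SimAxonConfig(corridor_width_um=0.5, punctum_area_um2_range=(0.3, 0.45))
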