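import numpy as np
import pytest

from microlapse import (
    CellConfig,
    ConfigError,
    DirtConfig,
    DriftConfig,
    NoiseConfig,
    SimConfig,
    drift_model,
    simulate_defocus_series,
    simulate_timelapse,
    tenengrad,
)


class TestDriftModel:
    def test_starts_at_zero(self):
        np.testing.assert_array_equal(drift_model(0.0, (10, -5), 100.0), [0.0, 0.0])

    def test_asymptote(self):
        np.testing.assert_allclose(drift_model(1e9, (10, -5), 100.0), [10.0, -5.0])

    def test_one_time_constant(self):
        expected = 10.0 * (1 - np.exp(-1.0))
        np.testing.assert_allclose(drift_model(100.0, (10, 0), 100.0), [expected, 0.0])

    def test_bad_tau(self):
        with pytest.raises(ValueError):
            drift_model(1.0, (1, 1), 0.0)


class TestSimulateTimelapse:
    def test_disturbance_free_frames_identical(self, quiet_stack):
        stack, truth = quiet_stack
        first = stack[0].pixels
        for f in stack:
            np.testing.assert_array_equal(f.pixels, first)
        np.testing.assert_array_equal(truth.true_shift, 0.0)

    def test_seed_reproducibility(self):
        cfg = dict(shape=(64, 64), n_frames=6, dark_frames=0.2)
        a, _ = simulate_timelapse(SimConfig(seed=5, **cfg))
        b, _ = simulate_timelapse(SimConfig(seed=5, **cfg))
        c, _ = simulate_timelapse(SimConfig(seed=6, **cfg))
        np.testing.assert_array_equal(a.as_array(), b.as_array())
        assert not np.array_equal(a.as_array(), c.as_array())

    def test_noise_toggle_keeps_drift_realization(self):
        base = dict(shape=(64, 64), n_frames=6, dark_frames=None)
        _, t1 = simulate_timelapse(SimConfig(seed=3, **base))
        _, t2 = simulate_timelapse(
            SimConfig(seed=3, noise=NoiseConfig(enabled=False), **base)
        )
        np.testing.assert_array_equal(t1.true_shift, t2.true_shift)

    def test_dark_and_corrupted_bookkeeping(self):
        cfg = SimConfig(
            shape=(64, 64), n_frames=10, seed=2, dark_frames=[1, 4], corrupt_frames=[7]
        )
        stack, truth = simulate_timelapse(cfg)
        assert list(np.flatnonzero(truth.dark)) == [1, 4]
        assert list(np.flatnonzero(truth.corrupted)) == [7]
        # dark frames are ~5% of a normal frame's level; corrupted saturate
        normal_mean = stack[0].pixels.mean()
        assert stack[1].pixels.mean() == pytest.approx(0.05 * normal_mean, rel=0.25)
        assert np.all(stack[7].pixels == cfg.saturation_level)

    def test_ground_truth_gain_is_product(self):
        _, truth = simulate_timelapse(SimConfig(shape=(64, 64), n_frames=2, seed=9))
        np.testing.assert_array_equal(truth.gain, truth.vignette * truth.dirt_mask)
        assert truth.vignette.min() > 0 and truth.dirt_mask.min() > 0

    def test_poisson_mean_converges_to_clean_scene(self):
        common = dict(
            shape=(32, 32),
            n_frames=300,
            drift=DriftConfig(S_inf=(0, 0), jitter_px=0),
            cells=CellConfig(n=2, motion_px_per_frame=0, growth_per_hour=0),
            dark_frames=None,
        )
        noisy, _ = simulate_timelapse(
            SimConfig(seed=4, noise=NoiseConfig(photons_per_unit=2.0, read_sd=1.0), **common)
        )
        clean, _ = simulate_timelapse(
            SimConfig(seed=4, noise=NoiseConfig(enabled=False), **common)
        )
        sample_mean = noisy.as_array().mean(axis=0)
        scene = clean[0].pixels
        # per-pixel sd of the mean: sqrt(scene/ppu + read^2) / sqrt(n)
        sd_mean = np.sqrt(scene / 2.0 + 1.0) / np.sqrt(300)
        assert np.all(np.abs(sample_mean - scene) < 3.5 * sd_mean + 1e-9)

    def test_cell_area_ground_truth_linear(self):
        cfg = SimConfig(
            shape=(64, 64),
            n_frames=5,
            frame_interval_s=3600.0,
            seed=1,
            cells=CellConfig(n=3, A0_um2=100.0, growth_per_hour=0.1),
            dark_frames=None,
        )
        _, truth = simulate_timelapse(cfg)
        np.testing.assert_allclose(truth.cell_area_um2[:, 0], 100.0 * (1 + 0.1 * np.arange(5)))

    @pytest.mark.parametrize(
        "field,value",
        [
            ("vignetting_strength", 1.5),
            ("dark_frames", [999]),
            ("corrupt_frames", [-1]),
        ],
    )
    def test_config_validation(self, field, value):
        with pytest.raises(ConfigError):
            simulate_timelapse(SimConfig(shape=(32, 32), n_frames=4, seed=0, **{field: value}))

    def test_bayer_sampling_even_dims_and_site_gains(self):
        cfg = SimConfig(
            shape=(64, 64),
            n_frames=1,
            seed=8,
            bayer="BGGR",
            noise=NoiseConfig(enabled=False),
            dark_frames=None,
        )
        stack, _ = simulate_timelapse(cfg)
        mono, _ = simulate_timelapse(
            SimConfig(
                shape=(64, 64), n_frames=1, seed=8, noise=NoiseConfig(enabled=False),
                dark_frames=None,
            )
        )
        px, ref = stack[0].pixels, mono[0].pixels
        # BGGR: green sites at (0,1) and (1,0) pass unattenuated
        np.testing.assert_array_equal(px[0::2, 1::2], ref[0::2, 1::2])
        np.testing.assert_array_equal(px[1::2, 0::2], ref[1::2, 0::2])
        assert np.all(px[0::2, 0::2] < ref[0::2, 0::2])


class TestDefocusSeries:
    def test_true_focus_is_sharpest(self):
        cfg = SimConfig(shape=(96, 96), seed=5)
        zs = list(np.linspace(-5, 5, 11))
        series = simulate_defocus_series(cfg, zs, z_true=1.0, blur_per_z=1.0)
        scores = [tenengrad(f).value for f in series]
        assert zs[int(np.argmax(scores))] == 1.0

    def test_symmetric_about_focus(self):
        cfg = SimConfig(shape=(64, 64), seed=5)
        series = simulate_defocus_series(cfg, [-2.0, 0.0, 2.0], z_true=0.0, blur_per_z=1.5)
        np.testing.assert_allclose(series[0].pixels, series[2].pixels)

    def test_monotone_in_blur(self):
        cfg = SimConfig(shape=(96, 96), seed=5)
        series = simulate_defocus_series(cfg, list(range(6)), z_true=0.0, blur_per_z=1.0)
        scores = [tenengrad(f).value for f in series]
        assert all(a > b for a, b in zip(scores, scores[1:]))
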