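import numpy as np
import pytest

from microlapse import (
    CellConfig,
    DriftConfig,
    Frame,
    ImageStack,
    NoiseConfig,
    SimConfig,
    apply_flatfield,
    compute_flatfield,
    estimate_background,
    simulate_timelapse,
    temporal_mean,
)
from microlapse.errors import DegenerateInput, ShapeMismatch
from microlapse.flatfield import FlatField


def _blank_sim(seed=2, n_frames=40, noise=True, background=400.0):
    return SimConfig(
        shape=(96, 96),
        n_frames=n_frames,
        seed=seed,
        background=background,
        cells=CellConfig(n=0),
        drift=DriftConfig(S_inf=(0, 0), jitter_px=0),
        noise=NoiseConfig(enabled=noise, photons_per_unit=4.0, read_sd=2.0),
        dark_frames=None,
        corrupt_frames=[],
    )


class TestTemporalMean:
    def test_constant_stack(self):
        f = Frame(pixels=np.full((6, 6), 3.0))
        assert np.all(temporal_mean(ImageStack(frames=[f, f, f])).pixels == 3.0)

    def test_alternating_frames(self):
        frames = [Frame(pixels=np.zeros((4, 4))), Frame(pixels=np.full((4, 4), 2.0))]
        np.testing.assert_array_equal(temporal_mean(ImageStack(frames=frames)).pixels, 1.0)

    def test_linearity(self, rng):
        arrays = [rng.random((8, 8)) for _ in range(5)]
        stack = ImageStack(frames=[Frame(pixels=a) for a in arrays])
        scaled = ImageStack(frames=[Frame(pixels=3.0 * a) for a in arrays])
        np.testing.assert_allclose(
            temporal_mean(scaled).pixels, 3.0 * temporal_mean(stack).pixels
        )


class TestEstimateBackground:
    def test_known_offset_recovered(self):
        # blank vignetted scene + additive offset; darkest pixels ~ offset
        stack, _ = simulate_timelapse(_blank_sim(noise=False, background=0.0))
        offset = 50.0
        shifted = stack.with_frames(
            [Frame(pixels=f.pixels + offset, index=f.index) for f in stack]
        )
        est = estimate_background(shifted, q=1.0)
        assert est == pytest.approx(offset, rel=0.05)

    def test_zero_background(self):
        stack, _ = simulate_timelapse(_blank_sim(noise=False, background=0.0))
        assert estimate_background(stack) == pytest.approx(0.0, abs=1e-9)

    def test_dark_frame_method_exact(self):
        stack, _ = simulate_timelapse(_blank_sim(noise=False))
        dark = np.full((96, 96), 7.5)
        out = estimate_background(stack, method="dark_frame", dark_frames=dark)
        np.testing.assert_array_equal(out, dark)

    def test_invalid_percentile(self):
        stack, _ = simulate_timelapse(_blank_sim(noise=False))
        with pytest.raises(ValueError):
            estimate_background(stack, q=150.0)


class TestComputeFlatfield:
    def test_noise_free_blank_gain_exact(self):
        stack, truth = simulate_timelapse(_blank_sim(noise=False))
        ff = compute_flatfield(stack, background=0.0)
        expected = truth.gain / truth.gain.mean()
        np.testing.assert_allclose(ff.gain, expected, atol=1e-9)
        assert ff.gain.mean() == pytest.approx(1.0, abs=1e-6)

    def test_epsilon_clamp_keeps_gain_positive(self):
        px = np.ones((8, 8))
        px[0, 0] = 0.0
        stack = ImageStack(frames=[Frame(pixels=px)] * 2)
        ff = compute_flatfield(stack)
        assert np.all(ff.gain > 0)

    def test_invariant_to_global_gain(self, rng):
        arrays = [rng.random((16, 16)) + 0.5 for _ in range(4)]
        s1 = ImageStack(frames=[Frame(pixels=a) for a in arrays])
        s2 = ImageStack(frames=[Frame(pixels=5.0 * a) for a in arrays])
        np.testing.assert_allclose(
            compute_flatfield(s1).gain, compute_flatfield(s2).gain, rtol=1e-12
        )

    def test_gain_recovery_under_noise(self):
        stack, truth = simulate_timelapse(_blank_sim(noise=True, n_frames=60))
        ff = compute_flatfield(stack, background=0.0)
        expected = truth.gain / truth.gain.mean()
        rms = np.sqrt(np.mean((ff.gain - expected) ** 2))
        assert rms <= 0.02

    def test_motile_cells_average_out(self):
        # dim, fast-moving cells leave < 2% RMS residue in the gain estimate
        cfg = SimConfig(
            shape=(96, 96),
            n_frames=300,
            seed=9,
            background=100.0,
            drift=DriftConfig(S_inf=(0, 0), jitter_px=0),
            cells=CellConfig(
                n=6, A0_um2=80, growth_per_hour=0.0, motion_px_per_frame=4.0, contrast=30
            ),
            noise=NoiseConfig(photons_per_unit=4.0, read_sd=2.0),
            dark_frames=None,
        )
        stack, truth = simulate_timelapse(cfg)
        ff = compute_flatfield(stack, background=0.0)
        expected = truth.gain / truth.gain.mean()
        assert np.sqrt(np.mean((ff.gain - expected) ** 2)) <= 0.02

    def test_degenerate_all_zero(self):
        stack = ImageStack(frames=[Frame(pixels=np.zeros((4, 4)))] * 2)
        with pytest.raises(DegenerateInput):
            compute_flatfield(stack)


class TestApplyFlatfield:
    def test_self_correction_flattens_blank_stack(self):
        stack, _ = simulate_timelapse(_blank_sim(noise=False))
        ff = compute_flatfield(stack, background=0.0)
        out = apply_flatfield(stack, ff)
        for f in out:
            assert f.pixels.std() / f.pixels.mean() <= 1e-6

    def test_unit_gain_identity(self, rng):
        f = Frame(pixels=rng.random((8, 8)))
        ff = FlatField(gain=np.ones((8, 8)), background=0.0, source_n_frames=1)
        np.testing.assert_array_equal(apply_flatfield(f, ff).pixels, f.pixels)

    def test_dirt_spot_restored(self):
        stack, truth = simulate_timelapse(_blank_sim(noise=True, n_frames=60))
        ff = compute_flatfield(stack, background=0.0)
        out = temporal_mean(apply_flatfield(stack, ff)).pixels
        spot = truth.dirt_mask < 0.6  # deep dirt interior
        clean = truth.dirt_mask > 0.99
        if spot.sum() >= 10:
            assert abs(out[spot].mean() - out[clean].mean()) / out[clean].mean() <= 0.03

    def test_shape_mismatch(self, rng):
        ff = FlatField(gain=np.ones((8, 8)), background=0.0, source_n_frames=1)
        with pytest.raises(ShapeMismatch):
            apply_flatfield(Frame(pixels=rng.random((9, 9))), ff)

    def test_corrected_blank_reestimates_to_unit_gain(self):
        stack, _ = simulate_timelapse(_blank_sim(noise=False))
        ff = compute_flatfield(stack, background=0.0)
        out = apply_flatfield(stack, ff)
        ff2 = compute_flatfield(out, background=0.0)
        np.testing.assert_allclose(ff2.gain, 1.0, atol=0.01)
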