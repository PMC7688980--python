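import warnings

import numpy as np
import pytest

from microlapse import (
    DegenerateInput,
    Frame,
    ImageStack,
    ROISpec,
    ShapeMismatch,
    apply_shifts,
    estimate_shift,
    select_reference,
    simulate_timelapse,
    summarize_drift,
    track_drift,
)
from microlapse.register import DriftTrack, ShiftVector


def spatial_correlation_argmax(ref: np.ndarray, mov: np.ndarray) -> tuple[int, int]:
    """Brute-force oracle: argmax over all integer circular shifts of the
    zero-mean spatial correlation sum_x ref(x) * mov(x + s)."""
    a = ref - ref.mean()
    b = mov - mov.mean()
    best, best_val = (0, 0), -np.inf
    n0, n1 = a.shape
    for dy in range(n0):
        for dx in range(n1):
            val = np.sum(a * np.roll(b, (-dy, -dx), axis=(0, 1)))
            if val > best_val:
                best_val, best = val, (dy, dx)
    dy, dx = best
    if dy > n0 / 2:
        dy -= n0
    if dx > n1 / 2:
        dx -= n1
    return dy, dx


def _track_of(shifts):
    return DriftTrack(reference_index=0, shifts=[ShiftVector(dy, dx) for dy, dx in shifts])


class TestEstimateShift:
    def test_self_shift_is_zero(self, rng):
        img = rng.random((32, 32))
        sv = estimate_shift(img, img)
        assert (sv.dy, sv.dx) == (0.0, 0.0)

    def test_integer_circular_shift_recovered_exactly(self, rng):
        img = rng.random((32, 32))
        moved = np.roll(img, (3, -2), axis=(0, 1))
        sv = estimate_shift(img, moved, subpixel=False)
        assert (sv.dy, sv.dx) == (3.0, -2.0)

    def test_matches_exhaustive_spatial_oracle(self, rng):
        for _ in range(10):
            img = rng.random((32, 32))
            shift = (int(rng.integers(-10, 11)), int(rng.integers(-10, 11)))
            moved = np.roll(img, shift, axis=(0, 1))
            sv = estimate_shift(img, moved, subpixel=False)
            assert (sv.dy, sv.dx) == spatial_correlation_argmax(img, moved)

    def test_antisymmetry(self, rng):
        a = rng.random((48, 48))
        b = np.roll(a, (5, 7), axis=(0, 1)) + 0.01 * rng.random((48, 48))
        fwd = estimate_shift(a, b)
        rev = estimate_shift(b, a)
        assert fwd.dy == pytest.approx(-rev.dy, abs=0.1)
        assert fwd.dx == pytest.approx(-rev.dx, abs=0.1)

    def test_independent_noise_low_confidence(self, rng):
        ratios_noise, ratios_match = [], []
        for _ in range(5):
            a, b = rng.random((64, 64)), rng.random((64, 64))
            ratios_noise.append(estimate_shift(a, b).peak_ratio)
            ratios_match.append(estimate_shift(a, np.roll(a, (2, 2), (0, 1))).peak_ratio)
        assert np.mean(ratios_noise) < 2.0  # near 1: no dominant peak
        assert min(ratios_match) > 5.0

    def test_degenerate_and_mismatched_inputs(self, rng):
        with pytest.raises(DegenerateInput):
            estimate_shift(np.ones((16, 16)), rng.random((16, 16)))
        with pytest.raises(ShapeMismatch):
            estimate_shift(rng.random((16, 16)), rng.random((16, 17)))


class TestTrackDrift:
    def test_static_stack_all_zero(self, quiet_stack):
        stack, _ = quiet_stack
        track = track_drift(stack, reference_index=0)
        np.testing.assert_allclose(track.as_array(), 0.0, atol=1e-9)

    def test_recovers_simulated_drift(self, drifting_stack):
        stack, truth = drifting_stack
        track = track_drift(stack, reference_index=0, subpixel=True)
        true_rel = truth.true_shift - truth.true_shift[0]
        rmse = np.sqrt(np.mean(np.sum((track.as_array() - true_rel) ** 2, axis=1)))
        assert rmse <= 0.5

    def test_roi_on_sensor_dirt_stays_put(self):
        # bright background makes the dirt shadows high-contrast fixed
        # features, as they are on a transmission microscope sensor
        from microlapse import CellConfig, DirtConfig, DriftConfig, SimConfig

        cfg = SimConfig(
            shape=(128, 128),
            n_frames=30,
            seed=27,
            background=200.0,
            drift=DriftConfig(S_inf=(9.0, -7.0), tau_s=400.0, jitter_px=0.0),
            dirt=DirtConfig(n_spots=4, radius_px=(8.0, 12.0), attenuation=0.5),
            cells=CellConfig(n=6, motion_px_per_frame=0.0, contrast=150.0),
            dark_frames=None,
        )
        stack, truth = simulate_timelapse(cfg)
        # place an ROI on the deepest dirt spot: sensor-fixed, so its track
        # should stay near zero while the whole frame follows the drift
        spot = np.unravel_index(np.argmin(truth.dirt_mask), truth.dirt_mask.shape)
        row = int(np.clip(spot[0] - 16, 0, stack.shape[0] - 32))
        col = int(np.clip(spot[1] - 16, 0, stack.shape[1] - 32))
        roi = ROISpec(row=row, col=col, height=32, width=32)
        track = track_drift(stack, reference_index=0, rois=[roi])
        roi_mags = [s.magnitude for s in track.roi_tracks[roi]]
        assert np.median(roi_mags) <= 1.0
        assert track.shifts[-1].magnitude > 5.0

    def test_skipped_frames_inherit_previous_shift(self, drifting_stack):
        stack, _ = drifting_stack
        track = track_drift(stack, reference_index=0, skip=[5])
        assert track.shifts[5] == track.shifts[4]

    def test_reference_frame_has_zero_shift(self, drifting_stack):
        stack, _ = drifting_stack
        track = track_drift(stack, reference_index=7)
        assert track.shifts[7].as_tuple() == (0.0, 0.0)

    def test_invalid_reference(self, quiet_stack):
        with pytest.raises(IndexError):
            track_drift(quiet_stack[0], reference_index=99)


class TestSelectReference:
    def test_zero_drift_returns_first_frame(self, quiet_stack):
        stack, _ = quiet_stack
        assert select_reference(stack, window=4, tol_px=0.5) == 0

    def test_exponential_settle_found_near_analytic_point(self):
        # shift increments of s(t) = S(1 - e^(-t/tau)) drop below tol at
        # t = tau * ln(rate0 / tol)
        tau, S = 8.0, 20.0
        t = np.arange(60, dtype=float)
        shifts = S * (1 - np.exp(-t / tau))
        track = _track_of([(s, 0.0) for s in shifts])
        tol = 0.25
        rate0 = S * (1 - np.exp(-1 / tau))
        analytic = tau * np.log(rate0 / tol)
        window = 5
        got = select_reference(track, window=window, tol_px=tol)
        assert abs(got - analytic) <= window

    def test_unbounded_drift_falls_back_with_warning(self):
        track = _track_of([(2.0 * i, 0.0) for i in range(20)])
        with pytest.warns(UserWarning, match="settle"):
            idx = select_reference(track, window=5, tol_px=0.5)
        assert idx == 15

    def test_window_longer_than_stack(self, quiet_stack):
        with pytest.raises(ValueError):
            select_reference(quiet_stack[0], window=100)


class TestApplyShifts:
    def test_zero_track_identity(self, quiet_stack):
        stack, _ = quiet_stack
        track = _track_of([(0.0, 0.0)] * len(stack))
        out = apply_shifts(stack, track)
        np.testing.assert_array_equal(out.as_array(), stack.as_array())

    def test_integer_shifts_restore_reference(self, rng):
        base = rng.random((40, 40))
        shifts = [(0, 0), (3, 1), (-2, 4)]
        frames = [Frame(pixels=np.roll(base, s, axis=(0, 1)), index=i) for i, s in enumerate(shifts)]
        stack = ImageStack(frames=frames)
        out = apply_shifts(stack, _track_of(shifts), fill=0.0)
        for f, (dy, dx) in zip(out, shifts):
            # interior region (margins hold fill) must equal the reference
            sl = (slice(5, 35), slice(5, 35))
            np.testing.assert_allclose(f.pixels[sl], base[sl])

    def test_fill_value_in_margins(self, rng):
        base = rng.random((20, 20)) + 1.0
        stack = ImageStack(frames=[Frame(pixels=np.roll(base, (4, 0), axis=(0, 1)))])
        out = apply_shifts(stack, _track_of([(4, 0)]), fill=0.0)
        assert np.all(out[0].pixels[-4:, :] == 0.0)

    def test_realignment_is_idempotent(self, drifting_stack):
        stack, _ = drifting_stack
        track = track_drift(stack, reference_index=0)
        aligned = apply_shifts(stack, track, fill=float(stack[0].pixels.mean()))
        retrack = track_drift(aligned, reference_index=0)
        assert np.max(np.abs(retrack.as_array())) <= 0.5

    def test_length_mismatch(self, quiet_stack):
        with pytest.raises(ShapeMismatch):
            apply_shifts(quiet_stack[0], _track_of([(0, 0)]))


class TestSummarizeDrift:
    def test_zero_track(self):
        s = summarize_drift(_track_of([(0, 0)] * 12), frame_interval_s=60.0)
        assert s.total_drift_px == 0.0
        assert s.settle_index == 0
        assert s.max_rate_px_per_frame == 0.0

    def test_linear_drift_rate_and_no_settle(self):
        k = 1.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = summarize_drift(_track_of([(k * i, 0) for i in range(30)]), frame_interval_s=10.0)
        assert s.max_rate_px_per_frame == pytest.approx(k)
        assert s.max_rate_px_per_s == pytest.approx(k / 10.0)
        assert s.settle_index is None

    def test_exponential_settle_total_drift(self):
        t = np.arange(80, dtype=float)
        shifts = [(10 * (1 - np.exp(-ti / 10.0)), 0.0) for ti in t]
        s = summarize_drift(_track_of(shifts), frame_interval_s=60.0, window=8, tol_px=0.2)
        assert s.total_drift_px == pytest.approx(10 * (1 - np.exp(-79 / 10.0)), rel=1e-6)
        analytic = 10.0 * np.log((10 * (1 - np.exp(-0.1))) / 0.2) / 1.0
        assert abs(s.settle_index - analytic) <= 8
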