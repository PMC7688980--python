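"""Cross-correlation drift estimation, tracking and compensation.

Shift estimation uses the normalized circular cross-correlation computed in
the frequency domain (mean-subtracted inputs, optional raised-cosine
apodization), with an optional 3-point parabolic sub-pixel refinement of the
integer peak. The sign convention is fixed throughout the package: a shift
``(dy, dx)`` means the moving frame appears displaced down/right by that
amount relative to the reference, i.e. ``moving(r, c) ~ reference(r - dy,
c - dx)``.

Drift tracking follows the long-term incubator workflow: every frame is
registered against one settled reference frame, both for the whole field of
view and for fixed-feature regions of interest (typically placed on dirt on
the sensor, which does not move with the sample and therefore isolates
sensor/camera motion from true sample drift).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import fourier_shift, median_filter

from .errors import DegenerateInput, ShapeMismatch
from .io import Frame, ImageStack

__all__ = [
    "ShiftVector",
    "ROISpec",
    "DriftTrack",
    "DriftSummary",
    "estimate_shift",
    "track_drift",
    "select_reference",
    "apply_shifts",
    "summarize_drift",
]


@dataclass(frozen=True)
class ShiftVector:
    """A (dy, dx) displacement in pixels plus a peak-confidence ratio."""

    dy: float
    dx: float
    peak_ratio: float = np.inf  # highest / second-highest correlation peak

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dy, self.dx))

    def as_tuple(self) -> tuple[float, float]:
        return (self.dy, self.dx)


@dataclass(frozen=True)
class ROISpec:
    """A rectangular region in sensor coordinates (row, col, height, width)."""

    row: int
    col: int
    height: int
    width: int
    role: str = "fixed_feature"  # or "sample"

    def validate(self, shape: tuple[int, int]) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError(f"ROI must be at least 16x16 px, got {self.height}x{self.width}")
        if (
            self.row < 0
            or self.col < 0
            or self.row + self.height > shape[0]
            or self.col + self.width > shape[1]
        ):
            raise ValueError(f"ROI {self} not fully inside frame of shape {shape}")

    def crop(self, pixels: np.ndarray) -> np.ndarray:
        return pixels[self.row : self.row + self.height, self.col : self.col + self.width]


@dataclass
class DriftTrack:
    reference_index: int
    shifts: list[ShiftVector]
    roi_tracks: dict[ROISpec, list[ShiftVector]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.shifts)

    def as_array(self) -> np.ndarray:
        return np.array([[s.dy, s.dx] for s in self.shifts])


@dataclass
class DriftSummary:
    total_drift_px: float
    settle_index: int | None
    settle_time_s: float | None
    max_rate_px_per_frame: float
    max_rate_px_per_s: float | None


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    """Vertex offset of the parabola through three equispaced samples."""
    denom = cm - 2.0 * c0 + cp
    if denom == 0:
        return 0.0
    off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_shift(reference, moving, subpixel: bool = True, apodize: bool = False) -> ShiftVector:
    """Estimate the displacement of ``moving`` relative to ``reference``.

    The normalized circular cross-correlation is computed via FFT on
    mean-subtracted inputs; the integer argmax gives the shift, refined per
    axis by a 3-point parabolic fit when ``subpixel``. ``peak_ratio`` is the
    ratio of the highest to the second-highest local correlation peak
    (correlation outside a 3x3 neighborhood of the maximum); values near 1
    indicate an unreliable estimate.
    """
    ref = reference.pixels if isinstance(reference, Frame) else np.asarray(reference, float)
    mov = moving.pixels if isinstance(moving, Frame) else np.asarray(moving, float)
    if ref.shape != mov.shape:
        raise ShapeMismatch(f"reference {ref.shape} vs moving {mov.shape}")
    a = ref - ref.mean()
    b = mov - mov.mean()
    if not a.any() or not b.any():
        raise DegenerateInput("cannot correlate a constant image")
    if apodize:
        wy = np.hanning(ref.shape[0])[:, None]
        wx = np.hanning(ref.shape[1])[None, :]
        a = a * wy * wx
        b = b * wy * wx
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    norm = np.sqrt(np.sum(np.abs(fa) ** 2) * np.sum(np.abs(fb) ** 2)) / a.size
    corr = np.fft.ifft2(fb * np.conj(fa)).real / norm

    peak_flat = int(np.argmax(corr))
    py, px = np.unravel_index(peak_flat, corr.shape)
    peak_val = corr[py, px]

    masked = corr.copy()
    ys = (np.arange(py - 1, py + 2)) % corr.shape[0]
    xs = (np.arange(px - 1, px + 2)) % corr.shape[1]
    masked[np.ix_(ys, xs)] = -np.inf
    second = float(masked.max())
    peak_ratio = float(peak_val / second) if second > 0 else np.inf

    dy, dx = float(py), float(px)
    if subpixel:
        n0, n1 = corr.shape
        dy += _parabolic_offset(
            corr[(py - 1) % n0, px], peak_val, corr[(py + 1) % n0, px]
        )
        dx += _parabolic_offset(
            corr[py, (px - 1) % n1], peak_val, corr[py, (px + 1) % n1]
        )
    # unwrap circular indices to signed shifts
    if dy > corr.shape[0] / 2:
        dy -= corr.shape[0]
    if dx > corr.shape[1] / 2:
        dx -= corr.shape[1]
    return ShiftVector(dy=dy, dx=dx, peak_ratio=peak_ratio)


def track_drift(
    stack: ImageStack,
    reference_index: int = 0,
    rois: Sequence[ROISpec] = (),
    subpixel: bool = True,
    skip: Sequence[int] = (),
) -> DriftTrack:
    """Register every frame against the reference frame.

    ROI tracks are computed on crops taken at the *same* sensor coordinates
    in reference and moving frames, so an ROI on a sensor-fixed feature
    (dirt) reads ~(0, 0) while the whole-frame track follows the sample
    drift. Frames listed in ``skip`` (e.g. QC-flagged) are not registered and
    inherit the previous valid shift, keeping downstream compensation total.
    """
    n = len(stack)
    if not (0 <= reference_index < n):
        raise IndexError(f"reference index {reference_index} outside stack of {n}")
    for roi in rois:
        roi.validate(stack.shape)
    skip_set = set(int(i) for i in skip)
    ref = stack[reference_index]

    shifts: list[ShiftVector] = []
    roi_tracks: dict[ROISpec, list[ShiftVector]] = {roi: [] for roi in rois}
    prev = ShiftVector(0.0, 0.0)
    prev_roi = {roi: ShiftVector(0.0, 0.0) for roi in rois}
    for i, frame in enumerate(stack):
        if i == reference_index:
            sv = ShiftVector(0.0, 0.0)
            shifts.append(sv)
            prev = sv
            for roi in rois:
                roi_tracks[roi].append(ShiftVector(0.0, 0.0))
                prev_roi[roi] = ShiftVector(0.0, 0.0)
            continue
        if i in skip_set:
            shifts.append(prev)
            for roi in rois:
                roi_tracks[roi].append(prev_roi[roi])
            continue
        sv = estimate_shift(ref, frame, subpixel=subpixel)
        shifts.append(sv)
        prev = sv
        for roi in rois:
            rv = estimate_shift(roi.crop(ref.pixels), roi.crop(frame.pixels), subpixel=subpixel)
            roi_tracks[roi].append(rv)
            prev_roi[roi] = rv
    return DriftTrack(reference_index=reference_index, shifts=shifts, roi_tracks=roi_tracks)


def _drift_increments(track_xy: np.ndarray, window: int) -> np.ndarray:
    """Per-frame drift-rate magnitudes of a jitter-suppressed track.

    Each shift component is smoothed with a rolling median over ``window``
    frames before differencing, so sub-pixel frame-to-frame jitter does not
    drown the slow thermal drift rate the settle rule is looking for.
    """
    if len(track_xy) < 2:
        return np.zeros(0)
    w = max(3, min(window, len(track_xy)))
    smooth = np.column_stack(
        [median_filter(track_xy[:, k], size=w, mode="nearest") for k in range(2)]
    )
    return np.linalg.norm(np.diff(smooth, axis=0), axis=1)


def _settle_index(increments: np.ndarray, window: int, tol_px: float) -> int | None:
    """First index i with median(increments[i:i+window]) < tol, else None."""
    n = len(increments)
    for i in range(0, n - window + 1):
        if np.median(increments[i : i + window]) < tol_px:
            return i
    return None


def select_reference(
    stack_or_track,
    window: int = 10,
    tol_px: float = 0.3,
    subpixel: bool = True,
) -> int:
    """Pick the first frame after which lateral drift has settled.

    A provisional track against frame 0 is computed (or an existing
    :class:`DriftTrack` reused); the chosen index is the first where the
    rolling median of per-frame shift increments stays below ``tol_px`` for
    ``window`` consecutive frames. ``tol_px`` must sit above the per-frame
    jitter floor (about 1.4x the jitter sd), otherwise nothing ever counts
    as settled. If the drift never settles the start of
    the final window is returned with a warning — mirroring the manual
    practice of picking a frame "after the heat-up phase".
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    if isinstance(stack_or_track, DriftTrack):
        track = stack_or_track
        n = len(track)
    else:
        stack = stack_or_track
        n = len(stack)
        if n < window:
            raise ValueError(f"stack of {n} frames shorter than window {window}")
        track = track_drift(stack, reference_index=0, subpixel=subpixel)
    arr = track.as_array()
    if n < window:
        raise ValueError(f"track of {n} frames shorter than window {window}")
    idx = _settle_index(_drift_increments(arr, window), window, tol_px)
    if idx is None:
        warnings.warn(
            f"drift never settled below {tol_px} px/frame; using start of final window",
            stacklevel=2,
        )
        return n - window
    return idx


def apply_shifts(stack: ImageStack, track: DriftTrack, fill: float = 0.0) -> ImageStack:
    """Translate each frame by minus its tracked shift, re-centering the series.

    Integer shifts use exact array translation (photometry-preserving);
    fractional shifts use a Fourier-domain translation. Margins vacated by
    the translation are set to ``fill``.
    """
    if len(track) != len(stack):
        raise ShapeMismatch(f"track length {len(track)} vs stack length {len(stack)}")
    out = []
    rows, cols = stack.shape
    for frame, sv in zip(stack, track.shifts):
        dy, dx = -sv.dy, -sv.dx
        iy, ix = int(round(dy)), int(round(dx))
        if abs(dy - iy) < 1e-9 and abs(dx - ix) < 1e-9:
            shifted = np.full((rows, cols), float(fill))
            src_y = slice(max(0, -iy), min(rows, rows - iy))
            src_x = slice(max(0, -ix), min(cols, cols - ix))
            dst_y = slice(max(0, iy), min(rows, rows + iy))
            dst_x = slice(max(0, ix), min(cols, cols + ix))
            shifted[dst_y, dst_x] = frame.pixels[src_y, src_x]
        else:
            shifted = np.fft.ifftn(fourier_shift(np.fft.fftn(frame.pixels), (dy, dx))).real
            # blank the circularly wrapped margins
            my, mx = int(np.ceil(abs(dy))), int(np.ceil(abs(dx)))
            if my:
                if dy > 0:
                    shifted[:my, :] = fill
                else:
                    shifted[-my:, :] = fill
            if mx:
                if dx > 0:
                    shifted[:, :mx] = fill
                else:
                    shifted[:, -mx:] = fill
        out.append(replace(frame, pixels=shifted))
    return stack.with_frames(out)


def summarize_drift(
    track: DriftTrack,
    frame_interval_s: float | None = None,
    window: int = 10,
    tol_px: float = 0.3,
) -> DriftSummary:
    """Total drift, settle point and peak drift rate of a track."""
    arr = track.as_array()
    total = float(np.linalg.norm(arr[-1] - arr[0]))
    increments = np.linalg.norm(np.diff(arr, axis=0), axis=1)
    max_rate = float(increments.max()) if len(increments) else 0.0
    settle: int | None
    drift_rates = _drift_increments(arr, window)
    if len(drift_rates) >= window:
        settle = _settle_index(drift_rates, window, tol_px)
        if settle is None:
            warnings.warn("drift never settled within tolerance", stacklevel=2)
    else:
        settle = 0 if max_rate < tol_px else None
    return DriftSummary(
        total_drift_px=total,
        settle_index=settle,
        settle_time_s=None
        if settle is None or frame_interval_s is None
        else settle * frame_interval_s,
        max_rate_px_per_frame=max_rate,
        max_rate_px_per_s=None if frame_interval_s is None else max_rate / frame_interval_s,
    )
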