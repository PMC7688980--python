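"""Flat-field (gain) estimation from the temporal stack mean.

On a long time-lapse, moving objects average out of the pixelwise temporal
mean, leaving only the sensor-fixed patterns: illumination vignetting, dirt
and scratches. Dividing each background-corrected frame by that mean (after
normalizing it to unit spatial mean) therefore removes shading and dirt in
one step — no separate blank/flat acquisition is needed.

The gain is estimated and applied in *raw sensor coordinates*, before any
drift alignment: vignetting and dirt are fixed to the sensor, so aligning
first would smear them across the field. An ``aligned`` mode exists for
comparison (see :func:`compute_flatfield`'s caller in the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateInput, EmptyInput, ShapeMismatch
from .io import Frame, ImageStack

__all__ = [
    "FlatField",
    "estimate_background",
    "compute_flatfield",
    "apply_flatfield",
    "temporal_mean",
]

_EPS_FRACTION = 1e-6  # gain clamp relative to the gain maximum


@dataclass
class FlatField:
    """Multiplicative gain (spatial mean 1, strictly positive) + additive background."""

    gain: np.ndarray
    background: float | np.ndarray
    source_n_frames: int

    def __post_init__(self) -> None:
        if np.any(self.gain <= 0):
            raise ValueError("FlatField gain must be strictly positive")
        m = float(self.gain.mean())
        if abs(m - 1.0) > 1e-6:
            raise ValueError(f"FlatField gain must have spatial mean 1, got {m}")


def temporal_mean(stack: ImageStack) -> Frame:
    """Pixelwise mean across all frames of a stack."""
    if len(stack) == 0:
        raise EmptyInput("cannot average an empty stack")
    mean = stack.as_array().mean(axis=0)
    f0 = stack[0]
    return replace(f0, pixels=mean, index=0, timestamp_s=0.0)


def estimate_background(
    stack: ImageStack,
    method: str = "percentile",
    q: float = 1.0,
    dark_frames: np.ndarray | None = None,
) -> float | np.ndarray:
    """Estimate the additive background offset.

    ``percentile``: the q-th percentile (default 1) of all pixels, a scalar —
    robust when the scene contains genuinely empty regions near zero signal.
    ``dark_frame``: the mean of supplied camera-dark frames (a 2-D map),
    for setups where real dark acquisitions exist.
    """
    if len(stack) == 0:
        raise EmptyInput("cannot estimate background from an empty stack")
    if method == "percentile":
        if not (0 <= q <= 100):
            raise ValueError(f"percentile q must be in [0, 100], got {q}")
        return float(np.percentile(stack.as_array(), q))
    if method == "dark_frame":
        if dark_frames is None:
            raise ValueError("dark_frame method requires dark_frames")
        darks = np.asarray(dark_frames, dtype=float)
        if darks.ndim == 2:
            return darks
        return darks.mean(axis=0)
    raise ValueError(f"unknown background method {method!r}")


def compute_flatfield(stack: ImageStack, background: float | np.ndarray = 0.0) -> FlatField:
    """Estimate the gain image as the normalized temporal mean.

    gain = clamp(mean_t(frame - background), eps) / spatial_mean, with
    ``eps = 1e-6 x max``; the clamp keeps the gain strictly positive even
    where the mean is zero. The result is invariant to a global intensity
    gain of the stack.
    """
    mean = temporal_mean(stack).pixels - background
    peak = float(mean.max())
    if peak <= 0:
        raise DegenerateInput("temporal mean is non-positive everywhere")
    eps = _EPS_FRACTION * peak
    gain = np.clip(mean, eps, None)
    gain = gain / gain.mean()
    return FlatField(gain=gain, background=background, source_n_frames=len(stack))


def apply_flatfield(stack_or_frame, ff: FlatField):
    """Correct frames: ``(input - background) / gain``.

    Values are *not* clipped — output may dip below zero near the noise
    floor, preserving linearity for downstream statistics; integer export is
    where clipping happens.
    """
    def _one(frame: Frame) -> Frame:
        if frame.pixels.shape != ff.gain.shape:
            raise ShapeMismatch(
                f"frame shape {frame.pixels.shape} vs gain shape {ff.gain.shape}"
            )
        return replace(frame, pixels=(frame.pixels - ff.background) / ff.gain)

    if isinstance(stack_or_frame, Frame):
        return _one(stack_or_frame)
    return stack_or_frame.with_frames([_one(f) for f in stack_or_frame])
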