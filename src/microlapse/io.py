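"""Image input/output and channel handling.

The unit of processing everywhere in this package is a single-channel
:class:`Frame`; ordered collections of frames form an :class:`ImageStack`.
Color data enters either as RGB planes or as a raw Bayer mosaic with a
declared filter pattern, and is reduced to the green channel before any
quantitative step, since the green sites dominate sensitivity on single-chip
color sensors and give one well-defined intensity channel.

Conventions: arrays are row-major ``(row, col)``, origin at the top-left,
0-based indices throughout.
"""

from __future__ import annotations

import glob as _glob
import os
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import EmptyInput, ReadError, ShapeError, ShapeMismatch

__all__ = [
    "Frame",
    "ImageStack",
    "BayerMosaic",
    "read_sequence",
    "write_stack",
    "write_preview_pngs",
    "extract_green",
    "bin_frame",
    "make_preview",
]

_BAYER_PATTERNS = ("RGGB", "BGGR", "GRBG", "GBRG")


@dataclass
class Frame:
    """One single-channel image with its acquisition metadata.

    Parameters
    ----------
    pixels
        2-D array of nonnegative, finite intensities in arbitrary linear units.
    timestamp_s
        Seconds since the start of the acquisition.
    index
        0-based frame number within the original acquisition (preserved even
        after frames are dropped by quality control).
    pixel_size_um
        Micrometers per pixel, if known.
    channel
        One of ``gray``, ``red``, ``green``, ``blue``.
    """

    pixels: np.ndarray
    timestamp_s: float = 0.0
    index: int = 0
    pixel_size_um: float | None = None
    channel: str = "gray"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ShapeError(f"Frame pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Frame pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageStack:
    """An ordered time-lapse of same-shaped frames."""

    frames: list[Frame]
    frame_interval_s: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise EmptyInput("ImageStack requires at least one frame")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.shape != shape:
                raise ShapeMismatch(
                    f"frame {f.index} has shape {f.shape}, expected {shape}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def pixel_size_um(self) -> float | None:
        return self.frames[0].pixel_size_um

    def as_array(self) -> np.ndarray:
        """Stack pixel data into a (n_frames, rows, cols) array."""
        return np.stack([f.pixels for f in self.frames])

    def with_frames(self, frames: Sequence[Frame]) -> "ImageStack":
        return ImageStack(
            frames=list(frames),
            frame_interval_s=self.frame_interval_s,
            provenance=dict(self.provenance),
        )


@dataclass
class BayerMosaic:
    """A raw color-filter-array image with a declared 2x2 pattern.

    The pattern is never guessed from data; it must be stated by the caller
    (e.g. ``BGGR`` for the Raspberry Pi v2 sensor).
    """

    raw: np.ndarray
    pattern: str

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2:
            raise ShapeError(f"Bayer mosaic must be 2-D, got shape {self.raw.shape}")
        if self.raw.shape[0] % 2 or self.raw.shape[1] % 2:
            raise ShapeMismatch(
                f"Bayer mosaic needs even dimensions, got {self.raw.shape}"
            )
        if self.pattern not in _BAYER_PATTERNS:
            raise ValueError(
                f"unknown Bayer pattern {self.pattern!r}; expected one of {_BAYER_PATTERNS}"
            )


def _natural_key(name: str) -> tuple:
    """Sort key splitting digit runs so frame_2 < frame_10; ties lexicographic."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _read_one(path: str) -> np.ndarray:
    try:
        return np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the filename
        raise ReadError(f"could not read image file {path!r}: {exc}") from exc


def read_sequence(
    path_or_glob: str,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Read a time-lapse from a multi-page TIFF, a directory, or a glob.

    Frames are ordered by page order (multi-page TIFF) or by natural sort of
    filenames. When timestamps are not available from metadata they default to
    ``index * frame_interval_s`` (or the index itself if no interval is given).
    Multichannel images are kept as-is in a channel-last array only long enough
    to extract a plane; this reader returns grayscale frames for 2-D inputs and
    raises for inputs it cannot reduce — pass RGB through
    :func:`extract_green` instead by reading the file yourself.
    """
    paths: list[str]
    if os.path.isdir(path_or_glob):
        paths = sorted(
            (
                os.path.join(path_or_glob, n)
                for n in os.listdir(path_or_glob)
                if n.lower().endswith((".tif", ".tiff", ".png", ".jpg", ".jpeg"))
            ),
            key=lambda p: _natural_key(os.path.basename(p)),
        )
    elif any(ch in path_or_glob for ch in "*?["):
        paths = sorted(_glob.glob(path_or_glob), key=lambda p: _natural_key(os.path.basename(p)))
    elif os.path.exists(path_or_glob):
        paths = [path_or_glob]
    else:
        paths = []
    if not paths:
        raise FileNotFoundError(f"no image files match {path_or_glob!r}")

    arrays: list[np.ndarray] = []
    if len(paths) == 1 and paths[0].lower().endswith((".tif", ".tiff")):
        try:
            data = tifffile.imread(paths[0])
        except Exception as exc:  # noqa: BLE001
            raise ReadError(f"could not read image file {paths[0]!r}: {exc}") from exc
        if data.ndim == 2:
            arrays = [data]
        elif data.ndim == 3:
            arrays = [data[i] for i in range(data.shape[0])]
        else:
            raise ShapeError(f"unsupported TIFF dimensionality {data.shape}")
    else:
        arrays = [_read_one(p) for p in paths]

    shape = arrays[0].shape
    for p, a in zip(paths * (len(arrays) if len(paths) == 1 else 1), arrays):
        if a.shape != shape:
            raise ShapeMismatch(
                f"frame shape {a.shape} in {p!r} differs from first frame {shape}"
            )

    interval = frame_interval_s if frame_interval_s is not None else 1.0
    frames = []
    for i, a in enumerate(arrays):
        a = np.asarray(a, dtype=float)
        if a.ndim == 3:  # RGB(A): keep the green plane; alpha ignored
            a = a[..., 1]
        frames.append(
            Frame(
                pixels=a,
                timestamp_s=i * interval,
                index=i,
                pixel_size_um=pixel_size_um,
            )
        )
    return ImageStack(
        frames=frames,
        frame_interval_s=frame_interval_s,
        provenance={"paths": paths, "pixel_size_um": pixel_size_um},
    )


def write_stack(stack: ImageStack, path: str, dtype: str = "uint16") -> None:
    """Write a stack as a multi-page TIFF.

    Float data is clipped to the target integer range at export; values are
    not rescaled, so a 16-bit round trip of 16-bit-ranged data is lossless.
    """
    data = stack.as_array()
    if dtype == "uint16":
        out = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    elif dtype == "uint8":
        out = np.clip(np.rint(data), 0, 255).astype(np.uint8)
    elif dtype == "float32":
        out = data.astype(np.float32)
    else:
        raise ValueError(f"unsupported export dtype {dtype!r}")
    # explicit photometric: 3- or 4-frame stacks must not be guessed as RGB
    tifffile.imwrite(path, out, photometric="minisblack")


def extract_green(frame) -> Frame:
    """Reduce a frame to its green channel.

    * Grayscale frames pass through unchanged.
    * RGB arrays (or Frames wrapping them is not supported — RGB enters as a
      raw ndarray) return the green plane.
    * Bayer mosaics return the mean of the two green sites of each 2x2 tile,
      at half resolution; no demosaicing interpolation is performed, so no
      intensities are fabricated.
    """
    if isinstance(frame, BayerMosaic):
        raw, pattern = frame.raw, frame.pattern
        tiles = {
            "RGGB": ((0, 1), (1, 0)),
            "BGGR": ((0, 1), (1, 0)),
            "GRBG": ((0, 0), (1, 1)),
            "GBRG": ((0, 0), (1, 1)),
        }[pattern]
        (r0, c0), (r1, c1) = tiles
        g = 0.5 * (raw[r0::2, c0::2] + raw[r1::2, c1::2])
        return Frame(pixels=g, channel="green")
    if isinstance(frame, Frame):
        if frame.channel in ("gray", "green"):
            return frame
        raise ValueError(f"cannot extract green from a {frame.channel} frame")
    arr = np.asarray(frame, dtype=float)
    if arr.ndim == 2:
        return Frame(pixels=arr, channel="gray")
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        return Frame(pixels=arr[..., 1], channel="green")
    raise ShapeError(f"cannot interpret array of shape {arr.shape} as an image")


def bin_frame(frame: Frame, factor: int) -> Frame:
    """Mean-bin a frame over non-overlapping ``factor x factor`` blocks.

    Trailing rows/columns that do not fill a whole block are cropped rather
    than padded, so no intensities are fabricated. ``pixel_size_um`` scales by
    the factor. The global mean over the retained region is conserved exactly
    (up to floating-point rounding).
    """
    if factor < 1:
        raise ValueError(f"bin factor must be >= 1, got {factor}")
    if factor == 1:
        return frame
    r, c = frame.shape
    rr, cc = (r // factor) * factor, (c // factor) * factor
    cropped = frame.pixels[:rr, :cc]
    binned = cropped.reshape(rr // factor, factor, cc // factor, factor).mean(axis=(1, 3))
    return replace(
        frame,
        pixels=binned,
        pixel_size_um=None if frame.pixel_size_um is None else frame.pixel_size_um * factor,
    )


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        return np.zeros_like(pixels, dtype=np.uint8)
    return np.clip(np.rint((pixels - lo) / (hi - lo) * 255.0), 0, 255).astype(np.uint8)


def make_preview(stack: ImageStack, stride: int = 10, scale: float = 1.0) -> ImageStack:
    """Subsample every ``stride``-th frame and rescale for a quick-look series.

    Previews are intensity-normalized to the 8-bit range per frame; they are
    for inspection only and carry no quantitative meaning.
    """
    if len(stack) == 0:
        raise EmptyInput("cannot preview an empty stack")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if not (0 < scale <= 1):
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    previews = []
    for f in stack.frames[::stride]:
        px = f.pixels
        if scale < 1.0:
            from skimage.transform import rescale

            px = rescale(px, scale, anti_aliasing=True, preserve_range=True)
        previews.append(replace(f, pixels=_to_uint8(px).astype(float)))
    return stack.with_frames(previews)


def write_preview_pngs(preview: ImageStack, outdir: str, prefix: str = "preview") -> list[str]:
    """Export a preview stack as numbered 8-bit PNGs; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for i, f in enumerate(preview.frames):
        path = os.path.join(outdir, f"{prefix}_{i:05d}.png")
        iio.imwrite(path, np.clip(f.pixels, 0, 255).astype(np.uint8))
        paths.append(path)
    return paths
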