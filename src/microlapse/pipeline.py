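"""End-to-end long-term time-lapse processing.

Stage order (fixed convention, see docs/methods.md for the rationale):

1.  read the sequence
2.  extract the green channel (Bayer/RGB inputs)
3.  bin
4.  preview export
5.  per-frame statistics
6.  QC flagging and filtering
7.  background + flat-field estimation in raw sensor coordinates
8.  provisional drift track -> automatic reference selection (unless
    overridden), then drift tracking against the reference (whole frame +
    fixed-feature ROIs), all on the raw QC-filtered frames
9.  flat-field application
10. shift compensation
11. temporal mean of the aligned, corrected stack
12. drift summary

Both the gain estimate and the drift track are computed in raw sensor
coordinates. Vignetting and dirt are fixed to the sensor, so aligning
first would smear them and make them uncorrectable by a single gain image;
conversely the fixed-feature ROIs (dirt) only exist on raw frames — the
whole point of flat-fielding is to remove them. Every run writes a manifest with the full configuration,
per-stage artifact checksums and frame accounting, so a run is reproducible
from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import MicrolapseError
from .flatfield import apply_flatfield, compute_flatfield, estimate_background, temporal_mean
from .io import (
    ImageStack,
    bin_frame,
    make_preview,
    read_sequence,
    write_preview_pngs,
    write_stack,
)
from .qc import compute_stats, filter_stack, flag_frames
from .register import ROISpec, apply_shifts, select_reference, summarize_drift, track_drift

__all__ = ["PipelineConfig", "RunManifest", "run_timelapse"]


@dataclass
class PipelineConfig:
    input: str  # path, directory or glob (ignored when a stack is passed in)
    outdir: str
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None
    bin_factor: int = 1
    bayer_pattern: str | None = None  # input frames are raw mosaics of this pattern
    preview_stride: int = 10
    preview_scale: float = 1.0
    focus_metric: str = "tenengrad"
    dark_factor: float = 0.5
    robust_z: float = 10.0
    reference_index: int | None = None  # None = automatic settle detection
    settle_window: int = 10
    settle_tol_px: float = 0.3
    rois: list[ROISpec] = field(default_factory=list)
    subpixel: bool = True
    background_method: str = "percentile"
    background_q: float = 1.0
    ff_coords: str = "raw"  # "raw", "aligned", or "none" (skip correction)
    fill: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.bin_factor < 1:
            raise ValueError("bin_factor must be >= 1")
        if self.ff_coords not in ("raw", "aligned", "none"):
            raise ValueError(
                f"ff_coords must be 'raw', 'aligned' or 'none', got {self.ff_coords!r}"
            )


@dataclass
class RunManifest:
    config: dict
    version: str
    counts: dict
    checksums: dict
    warnings: list[str]
    error: str | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_track_csv(track, path: str) -> None:
    data = {
        "index": np.arange(len(track)),
        "dy": [s.dy for s in track.shifts],
        "dx": [s.dx for s in track.shifts],
        "peak_ratio": [s.peak_ratio for s in track.shifts],
    }
    for k, (roi, svs) in enumerate(track.roi_tracks.items()):
        data[f"roi{k}_dy"] = [s.dy for s in svs]
        data[f"roi{k}_dx"] = [s.dx for s in svs]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


def run_timelapse(config: PipelineConfig, stack: ImageStack | None = None) -> RunManifest:
    """Run the full pipeline; returns the manifest (also written to disk).

    ``stack`` may be passed directly (e.g. fresh from the simulator) to
    bypass the read stage; the manifest then records the in-memory source.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config),
        version=__version__,
        counts={},
        checksums={},
        warnings=[],
    )
    manifest_path = os.path.join(config.outdir, "manifest.json")

    def _save_manifest() -> None:
        with open(manifest_path, "w") as fh:
            fh.write(manifest.to_json())

    stage = "read"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            if stack is None:
                stack = read_sequence(
                    config.input,
                    pixel_size_um=config.pixel_size_um,
                    frame_interval_s=config.frame_interval_s,
                )
            manifest.counts["read"] = len(stack)

            stage = "extract_green"
            if config.bayer_pattern is not None:
                from dataclasses import replace as _replace

                from .io import BayerMosaic, extract_green

                stack = stack.with_frames(
                    [
                        _replace(
                            f,
                            pixels=extract_green(
                                BayerMosaic(raw=f.pixels, pattern=config.bayer_pattern)
                            ).pixels,
                            channel="green",
                        )
                        for f in stack
                    ]
                )

            stage = "bin"
            if config.bin_factor > 1:
                stack = stack.with_frames(
                    [bin_frame(f, config.bin_factor) for f in stack]
                )

            stage = "preview"
            preview = make_preview(stack, stride=config.preview_stride, scale=config.preview_scale)
            write_preview_pngs(preview, os.path.join(config.outdir, "preview"))

            stage = "stats"
            stats = compute_stats(stack, metric=config.focus_metric)
            stats_df = pd.DataFrame([asdict(s) for s in stats])
            stats_path = os.path.join(config.outdir, "stats.csv")
            stats_df.to_csv(stats_path, index=False, float_format="%.6f")

            stage = "qc"
            report = flag_frames(stats, dark_factor=config.dark_factor, robust_z=config.robust_z)
            qc_path = os.path.join(config.outdir, "qc.json")
            with open(qc_path, "w") as fh:
                json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            kept = filter_stack(stack, report)
            manifest.counts["excluded"] = report.n_excluded
            manifest.counts["kept"] = len(kept)

            stage = "flatfield"
            background = estimate_background(
                kept, method=config.background_method, q=config.background_q
            )
            if config.ff_coords == "raw":
                ff = compute_flatfield(kept, background)
            else:
                ff = None  # "aligned": estimated below; "none": never

            stage = "reference"
            if config.reference_index is not None:
                ref_idx = config.reference_index
            else:
                ref_idx = select_reference(
                    kept,
                    window=min(config.settle_window, max(2, len(kept) - 1)),
                    tol_px=config.settle_tol_px,
                    subpixel=config.subpixel,
                )
            manifest.counts["reference_index"] = int(ref_idx)

            stage = "track"
            track = track_drift(
                kept, reference_index=ref_idx, rois=config.rois, subpixel=config.subpixel
            )
            _write_track_csv(track, os.path.join(config.outdir, "track.csv"))

            stage = "apply_flatfield"
            corrected = apply_flatfield(kept, ff) if ff is not None else kept

            stage = "align"
            aligned = apply_shifts(corrected, track, fill=config.fill)
            if config.ff_coords == "aligned":
                ff = compute_flatfield(aligned, background)
                aligned = apply_flatfield(aligned, ff)

            stage = "export"
            write_stack(aligned, os.path.join(config.outdir, "aligned.tif"), dtype="float32")
            gain_stack = ImageStack(
                frames=[temporal_mean(aligned)], frame_interval_s=None
            )
            write_stack(gain_stack, os.path.join(config.outdir, "mean.tif"), dtype="float32")
            from .io import Frame as _Frame

            gain_img = ff.gain if ff is not None else np.ones(aligned.shape)
            write_stack(
                ImageStack(frames=[_Frame(pixels=gain_img)]),
                os.path.join(config.outdir, "gain.tif"),
                dtype="float32",
            )
            with open(os.path.join(config.outdir, "background.json"), "w") as fh:
                json.dump(
                    {
                        "background": float(background)
                        if np.isscalar(background)
                        else np.asarray(background).tolist(),
                        "method": config.background_method,
                    },
                    fh,
                    indent=2,
                )

            stage = "summary"
            summary = summarize_drift(
                track,
                frame_interval_s=config.frame_interval_s,
                window=min(config.settle_window, max(2, len(track) - 1)),
                tol_px=config.settle_tol_px,
            )
            with open(os.path.join(config.outdir, "drift_summary.json"), "w") as fh:
                json.dump(asdict(summary), fh, indent=2, sort_keys=True)

            manifest.warnings = [str(w.message) for w in caught]

        for name in (
            "stats.csv",
            "qc.json",
            "track.csv",
            "aligned.tif",
            "mean.tif",
            "gain.tif",
            "background.json",
            "drift_summary.json",
        ):
            manifest.checksums[name] = _sha256(os.path.join(config.outdir, name))
        _save_manifest()
        return manifest
    except (MicrolapseError, OSError, ValueError, IndexError, FileNotFoundError) as exc:
        manifest.error = f"stage {stage}: {exc}"
        _save_manifest()
        raise
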