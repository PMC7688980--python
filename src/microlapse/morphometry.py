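"""Cell segmentation and area/shape time-series summaries.

Segmentation is deliberately simple — Otsu's between-class-variance
threshold on a flat-field-corrected frame, 8-connected components, a minimum
area filter — suitable for well-contrasted adherent cells on a corrected
background. Per-object measurements follow the Fiji/ImageJ conventions the
field reports against:

* ``roundness = 4 A / (pi major_axis^2)`` — 1 for a circle, small for
  elongated objects (ImageJ "Round");
* ``circularity = 4 pi A / P^2`` — the perimeter-based shape factor.

Digitization lets both exceed 1 by a few percent on small objects; this is
expected and not clipped. Growth over time is summarized per time bin by
pooling all cell areas and reporting interpolated percentiles (10/25/50/75/90),
the usual whisker-plot statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .errors import EmptyInput
from .io import Frame

__all__ = [
    "CellRecord",
    "GrowthSummary",
    "GrowthBin",
    "segment_cells",
    "measure_cells",
    "growth_summary",
]


@dataclass
class CellRecord:
    frame_index: int
    label: int
    area_um2: float
    perimeter_um: float
    major_axis_um: float
    minor_axis_um: float
    roundness: float
    circularity: float
    centroid: tuple[float, float]  # (row, col) px


@dataclass
class GrowthBin:
    t_start_s: float
    t_end_s: float
    n_cells: int
    mean_area_um2: float
    p10: float
    p25: float
    p50: float
    p75: float
    p90: float


@dataclass
class GrowthSummary:
    bins: list[GrowthBin]
    missing_bins: list[int]


def segment_cells(frame, min_area_px: int = 20, polarity: str = "bright") -> np.ndarray:
    """Label connected cell-like objects by global Otsu thresholding.

    ``polarity`` states whether cells are brighter or darker than the
    background. A blank (constant) frame yields zero labels. Components
    smaller than ``min_area_px`` are removed and the remaining labels are
    renumbered 1..K.
    """
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    if polarity not in ("bright", "dark"):
        raise ValueError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    if np.ptp(px) == 0:
        return np.zeros(px.shape, dtype=int)
    thr = threshold_otsu(px)
    mask = px > thr if polarity == "bright" else px < thr
    labels = cc_label(mask, connectivity=2)
    if min_area_px > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area_px)
        labels[np.isin(labels, small)] = 0
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def measure_cells(
    labels: np.ndarray, pixel_size_um: float = 1.0, frame_index: int = 0
) -> list[CellRecord]:
    """Measure area, perimeter, ellipse axes and shape factors per label.

    Area is the exact pixel count times ``pixel_size_um**2``; the perimeter
    uses boundary-step weighting; the axes come from the second central
    moments (equivalent-ellipse convention).
    """
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    records = []
    for rp in regionprops(np.asarray(labels, dtype=int)):
        area = rp.area * pixel_size_um**2
        perim = rp.perimeter * pixel_size_um
        major = rp.axis_major_length * pixel_size_um
        minor = rp.axis_minor_length * pixel_size_um
        roundness = 4.0 * area / (np.pi * major**2) if major > 0 else 1.0
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 1.0
        records.append(
            CellRecord(
                frame_index=frame_index,
                label=int(rp.label),
                area_um2=float(area),
                perimeter_um=float(perim),
                major_axis_um=float(major),
                minor_axis_um=float(minor),
                roundness=float(roundness),
                circularity=float(circ),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
            )
        )
    return records


def growth_summary(
    records: list[CellRecord],
    bin_edges: np.ndarray,
    times_s: dict[int, float] | None = None,
) -> GrowthSummary:
    """Pool cell areas per time bin and report whisker-plot percentiles.

    ``bin_edges`` are in seconds; a record falls in bin ``i`` when
    ``edges[i] <= t < edges[i+1]``. ``times_s`` maps frame index to
    acquisition time; if omitted, the frame index itself is the time axis.
    Percentiles use linear interpolation between order statistics. Empty
    bins are skipped and reported in ``missing_bins`` with a warning.
    """
    if not records:
        raise EmptyInput("growth_summary needs at least one cell record")
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    t = np.array(
        [times_s[r.frame_index] if times_s else float(r.frame_index) for r in records]
    )
    areas = np.array([r.area_um2 for r in records])
    which = np.digitize(t, edges) - 1

    bins: list[GrowthBin] = []
    missing: list[int] = []
    for i in range(len(edges) - 1):
        sel = areas[which == i]
        if len(sel) == 0:
            missing.append(i)
            continue
        p10, p25, p50, p75, p90 = np.percentile(sel, [10, 25, 50, 75, 90])
        bins.append(
            GrowthBin(
                t_start_s=float(edges[i]),
                t_end_s=float(edges[i + 1]),
                n_cells=int(len(sel)),
                mean_area_um2=float(sel.mean()),
                p10=float(p10),
                p25=float(p25),
                p50=float(p50),
                p75=float(p75),
                p90=float(p90),
            )
        )
    if missing:
        warnings.warn(f"time bins with no cells: {missing}", stacklevel=2)
    return GrowthSummary(bins=bins, missing_bins=missing)
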