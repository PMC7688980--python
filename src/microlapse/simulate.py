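"""Synthetic incubator time-lapse acquisitions with exact ground truth.

The generator emulates the disturbance structure of a low-cost, 3D-printed
microscope running unattended inside a cell incubator for days:

* **Thermal drift** — the printed stage expands during the incubator's
  heat-up phase, so the field of view translates along an exponential-settle
  trajectory ``s(t) = S_inf * (1 - exp(-t/tau))`` plus per-frame jitter.
* **Sensor-fixed patterns** — illumination vignetting and dirt/scratches on
  the sensor window multiply the scene and do *not* move with the sample;
  this is what makes fixed-feature ROIs (placed on dirt) usable as a
  sensor-motion reference.
* **Frame dropouts** — sporadic dark frames (illumination dropout, x0.05)
  and corrupted frames (saturated readout).
* **Shot + read noise** — Poisson statistics at a configurable photon gain,
  then additive Gaussian read noise.
* **Cells** — soft-edged elliptical objects with linear area growth
  ``A(t) = A0 * (1 + g * t_hours)`` and a per-cell random walk, mimicking
  slowly growing, motile adherent cells imaged at one frame per minute.

Every stochastic element draws from an independent child stream of one seed,
so toggling one disturbance never changes the realization of another, and an
identical configuration reproduces bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, EmptyInput
from .io import Frame, ImageStack

__all__ = [
    "DriftConfig",
    "DirtConfig",
    "CellConfig",
    "NoiseConfig",
    "SimConfig",
    "GroundTruth",
    "drift_model",
    "simulate_timelapse",
    "simulate_defocus_series",
]


@dataclass
class DriftConfig:
    """Exponential-settle stage drift: asymptote, time constant, jitter."""

    S_inf: tuple[float, float] = (14.0, -14.0)  # (dy, dx) px, ~20 px magnitude
    tau_s: float = 3600.0  # one-hour incubator heat-up
    jitter_px: float = 0.3  # per-frame isotropic Gaussian sd


@dataclass
class DirtConfig:
    n_spots: int = 5
    radius_px: tuple[float, float] = (4.0, 10.0)
    attenuation: float = 0.5  # fractional gain dip at spot center


@dataclass
class CellConfig:
    n: int = 15
    A0_um2: float = 200.0
    growth_per_hour: float = 0.02  # fractional linear area growth
    motion_px_per_frame: float = 0.5  # random-walk step sd
    contrast: float = 100.0  # plateau intensity above background


@dataclass
class NoiseConfig:
    enabled: bool = True
    photons_per_unit: float = 2.0
    read_sd: float = 3.0


@dataclass
class SimConfig:
    """Full acquisition description; ``seed`` is mandatory."""

    shape: tuple[int, int] = (256, 256)
    n_frames: int = 100
    frame_interval_s: float = 60.0
    pixel_size_um: float = 1.0
    background: float = 10.0
    drift: DriftConfig = field(default_factory=DriftConfig)
    vignetting_strength: float = 0.3  # fractional falloff at corners
    dirt: DirtConfig = field(default_factory=DirtConfig)
    cells: CellConfig = field(default_factory=CellConfig)
    dark_frames: Sequence[int] | float | None = 0.05  # index list or probability
    corrupt_frames: Sequence[int] = field(default_factory=list)
    saturation_level: float = 4095.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    bayer: str | None = None  # off, or RGGB/BGGR/GRBG/GBRG
    defocus_blur_px: Sequence[float] | None = None  # per-frame blur sd schedule
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.drift.tau_s <= 0:
            raise ConfigError("drift.tau_s must be > 0")
        if not (0 <= self.vignetting_strength < 1):
            raise ConfigError("vignetting_strength must be in [0, 1)")
        if not (0 <= self.dirt.attenuation < 1):
            raise ConfigError("dirt.attenuation must be in [0, 1)")
        if self.cells.growth_per_hour < 0:
            raise ConfigError("cells.growth_per_hour must be nonnegative")
        if isinstance(self.dark_frames, (list, tuple)) and any(
            not (0 <= i < self.n_frames) for i in self.dark_frames
        ):
            raise ConfigError("dark_frames indices out of range")
        if any(not (0 <= i < self.n_frames) for i in self.corrupt_frames):
            raise ConfigError("corrupt_frames indices out of range")
        if self.defocus_blur_px is not None and len(self.defocus_blur_px) != self.n_frames:
            raise ConfigError("defocus_blur_px length must equal n_frames")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    true_shift: np.ndarray  # (n_frames, 2) float (dy, dx) px
    dark: np.ndarray  # (n_frames,) bool
    corrupted: np.ndarray  # (n_frames,) bool
    cell_area_um2: np.ndarray  # (n_frames, n_cells)
    vignette: np.ndarray  # gain image, strictly positive
    dirt_mask: np.ndarray  # gain image, strictly positive
    z_blur: np.ndarray  # (n_frames,) blur sd px

    @property
    def gain(self) -> np.ndarray:
        """The full sensor-fixed multiplicative field actually applied."""
        return self.vignette * self.dirt_mask


def drift_model(
    t: float | np.ndarray, S_inf: tuple[float, float], tau_s: float
) -> np.ndarray:
    """Exponential-settle shift ``s(t) = S_inf * (1 - exp(-t/tau))``, componentwise.

    Returns an array of shape ``(2,)`` for scalar ``t`` or ``(len(t), 2)``.
    """
    if tau_s <= 0:
        raise ValueError(f"tau_s must be > 0, got {tau_s}")
    t = np.asarray(t, dtype=float)
    factor = 1.0 - np.exp(-t / tau_s)
    return np.multiply.outer(factor, np.asarray(S_inf, dtype=float))


def _vignette_field(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Radial gain falloff, 1 at center, ``1 - strength`` at the corners."""
    r, c = shape
    yy, xx = np.mgrid[0:r, 0:c]
    cy, cx = (r - 1) / 2.0, (c - 1) / 2.0
    rho2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
    return 1.0 - strength * rho2


def _dirt_field(shape: tuple[int, int], cfg: DirtConfig, rng: np.random.Generator) -> np.ndarray:
    r, c = shape
    gain = np.ones(shape)
    yy, xx = np.mgrid[0:r, 0:c]
    for _ in range(cfg.n_spots):
        cy = rng.uniform(0.1 * r, 0.9 * r)
        cx = rng.uniform(0.1 * c, 0.9 * c)
        radius = rng.uniform(*cfg.radius_px)
        rho = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / radius
        # dirt sits on a cover window above the sensor, so its shadow is
        # optically defocused: ~3 px roll-off at the rim
        profile = 0.5 * (1.0 + np.tanh((1.0 - rho) * radius / 3.0))
        gain *= 1.0 - cfg.attenuation * profile
    return gain


def _place_cells(
    shape: tuple[int, int],
    ncells: int,
    margin: float,
    min_dist: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random cell centers with a minimum pairwise separation.

    Adherent cells spread side by side rather than stacking, so centers are
    rejection-sampled to keep at least ``min_dist`` apart; after 200 failed
    draws per cell the constraint is relaxed (dense fields stay usable).
    """
    rows, cols = shape
    centers: list[np.ndarray] = []
    for _ in range(ncells):
        best = None
        for _attempt in range(200):
            cand = np.array(
                [rng.uniform(margin, rows - margin), rng.uniform(margin, cols - margin)]
            )
            if not centers:
                best = cand
                break
            d = min(np.linalg.norm(cand - c) for c in centers)
            if d >= min_dist:
                best = cand
                break
            if best is None or d > min(
                np.linalg.norm(best - c) for c in centers
            ):
                best = cand
        centers.append(best)
    return np.array(centers).reshape(-1, 2)


def _render_cells(
    shape: tuple[int, int],
    centers: np.ndarray,  # (n_cells, 2) (row, col), already drifted
    areas_px: np.ndarray,  # (n_cells,)
    aspects: np.ndarray,
    thetas: np.ndarray,
    contrast: float,
) -> np.ndarray:
    """Render soft-edged ellipses of plateau ``contrast`` on a zero canvas.

    Each cell's half-maximum contour encloses exactly ``areas_px`` pixels of
    area (up to rasterization), which is the ground-truth morphometry target.
    """
    r, c = shape
    canvas = np.zeros(shape)
    for (cy, cx), area, q, th in zip(centers, areas_px, aspects, thetas):
        a = np.sqrt(area * q / np.pi)  # semi-major, px
        b = a / q
        pad = a + 4.0
        y0, y1 = int(max(0, np.floor(cy - pad))), int(min(r, np.ceil(cy + pad) + 1))
        x0, x1 = int(max(0, np.floor(cx - pad))), int(min(c, np.ceil(cx + pad) + 1))
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = np.cos(th) * dx + np.sin(th) * dy
        v = -np.sin(th) * dx + np.cos(th) * dy
        rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        edge = 1.0 / b  # ~1 px roll-off at the minor-axis rim
        canvas[y0:y1, x0:x1] += contrast * 0.5 * (1.0 + np.tanh((1.0 - rho) / edge))
    return canvas


def _bayer_sample(scene: np.ndarray, pattern: str) -> np.ndarray:
    """Sample a grayscale scene through a color filter mosaic.

    The scene is treated as the green-band intensity; red and blue sites see
    reduced transmission (x0.8 / x0.6), a crude but sufficient stand-in for a
    single-chip color sensor's spectral response.
    """
    site = {
        "RGGB": [["R", "G"], ["G", "B"]],
        "BGGR": [["B", "G"], ["G", "R"]],
        "GRBG": [["G", "R"], ["B", "G"]],
        "GBRG": [["G", "B"], ["R", "G"]],
    }[pattern]
    gains = {"R": 0.8, "G": 1.0, "B": 0.6}
    out = scene.copy()
    for i in range(2):
        for j in range(2):
            out[i::2, j::2] *= gains[site[i][j]]
    return out


def simulate_timelapse(config: SimConfig) -> tuple[ImageStack, GroundTruth]:
    """Generate a full synthetic acquisition and its ground truth.

    Per frame: cells are rendered at drifted positions, multiplied by the
    sensor-fixed vignette and dirt gains, optionally defocus-blurred,
    Poisson/read-noised, and Bayer-sampled if requested. Dark frames are
    scaled by 0.05 *before* noise (illumination dropout, statistics stay
    finite); corrupted frames are overwritten with the saturation level.
    """
    config.validate()
    rows, cols = config.shape
    n = config.n_frames

    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_jitter, rng_motion, rng_dark, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    vignette = _vignette_field(config.shape, config.vignetting_strength)
    dirt = _dirt_field(config.shape, config.dirt, rng_layout)
    gain = vignette * dirt

    ncells = config.cells.n
    margin = 0.12 * min(rows, cols)
    t = np.arange(n) * config.frame_interval_s
    area_end_px = (
        config.cells.A0_um2
        * (1.0 + config.cells.growth_per_hour * t[-1] / 3600.0)
        / config.pixel_size_um**2
    )
    a_max = np.sqrt(area_end_px * 2.0 / np.pi)  # semi-major at max aspect
    centers0 = _place_cells(config.shape, ncells, margin, 2.4 * a_max, rng_layout)
    aspects = rng_layout.uniform(1.0, 2.0, ncells)
    thetas = rng_layout.uniform(0, np.pi, ncells)
    shift = drift_model(t, config.drift.S_inf, config.drift.tau_s)
    if config.drift.jitter_px > 0:
        shift = shift + rng_jitter.normal(0.0, config.drift.jitter_px, (n, 2))

    steps = (
        rng_motion.normal(0.0, config.cells.motion_px_per_frame, (n, ncells, 2))
        if config.cells.motion_px_per_frame > 0
        else np.zeros((n, ncells, 2))
    )
    steps[0] = 0.0
    walks = np.cumsum(steps, axis=0)
    # reflect the random walk at the field margins: cells stay in the dish
    lim = np.array([rows - 2 * margin, cols - 2 * margin])
    folded = np.mod(walks + (centers0 - margin), 2 * lim)
    walks = np.where(folded > lim, 2 * lim - folded, folded) - (centers0 - margin)

    dark = np.zeros(n, dtype=bool)
    if isinstance(config.dark_frames, (list, tuple, np.ndarray)):
        dark[np.asarray(config.dark_frames, dtype=int)] = True
    elif config.dark_frames:
        dark = rng_dark.random(n) < float(config.dark_frames)
    corrupted = np.zeros(n, dtype=bool)
    if len(config.corrupt_frames):
        corrupted[np.asarray(list(config.corrupt_frames), dtype=int)] = True

    t_hours = t / 3600.0
    areas_um2 = config.cells.A0_um2 * (1.0 + config.cells.growth_per_hour * t_hours)
    cell_area_um2 = np.tile(areas_um2[:, None], (1, ncells))
    px_area_scale = config.pixel_size_um**2

    z_blur = (
        np.asarray(config.defocus_blur_px, dtype=float)
        if config.defocus_blur_px is not None
        else np.zeros(n)
    )

    frames = []
    for i in range(n):
        centers = centers0 + walks[i] + shift[i]
        scene = config.background + _render_cells(
            config.shape,
            centers,
            cell_area_um2[i] / px_area_scale,
            aspects,
            thetas,
            config.cells.contrast,
        )
        if z_blur[i] > 0:
            scene = gaussian_filter(scene, z_blur[i])
        scene = scene * gain
        if dark[i]:
            scene = scene * 0.05
        if config.bayer:
            scene = _bayer_sample(scene, config.bayer)
        if config.noise.enabled:
            ppu = config.noise.photons_per_unit
            scene = rng_noise.poisson(np.clip(scene, 0, None) * ppu) / ppu
            scene = scene + rng_noise.normal(0.0, config.noise.read_sd, scene.shape)
        else:
            # keep the noise sub-stream position independent of the toggle
            pass
        if corrupted[i]:
            scene = np.full(config.shape, config.saturation_level)
        frames.append(
            Frame(
                pixels=scene,
                timestamp_s=float(t[i]),
                index=i,
                pixel_size_um=config.pixel_size_um,
                channel="gray",
            )
        )

    stack = ImageStack(
        frames=frames,
        frame_interval_s=config.frame_interval_s,
        provenance={"simulated": True, "seed": config.seed},
    )
    truth = GroundTruth(
        true_shift=shift,
        dark=dark,
        corrupted=corrupted,
        cell_area_um2=cell_area_um2,
        vignette=vignette,
        dirt_mask=dirt,
        z_blur=z_blur,
    )
    return stack, truth


def simulate_defocus_series(
    config: SimConfig,
    z_positions: Sequence[float],
    z_true: float,
    blur_per_z: float,
) -> ImageStack:
    """Render one noise-free frame per axial position for autofocus testing.

    The blur sd is ``blur_per_z * |z - z_true|`` px, so sharpness metrics are
    maximal at the position closest to ``z_true`` and symmetric about it.
    """
    if len(z_positions) == 0:
        raise EmptyInput("z_positions must be nonempty")
    if blur_per_z < 0:
        raise ValueError(f"blur_per_z must be >= 0, got {blur_per_z}")
    config.validate()
    rng_layout = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    vignette = _vignette_field(config.shape, config.vignetting_strength)
    dirt = _dirt_field(config.shape, config.dirt, rng_layout)
    rows, cols = config.shape
    ncells = config.cells.n
    margin = 0.12 * min(rows, cols)
    a_max = np.sqrt(config.cells.A0_um2 / config.pixel_size_um**2 * 2.0 / np.pi)
    centers = _place_cells(config.shape, ncells, margin, 2.4 * a_max, rng_layout)
    aspects = rng_layout.uniform(1.0, 2.0, ncells)
    thetas = rng_layout.uniform(0, np.pi, ncells)
    base = config.background + _render_cells(
        config.shape,
        centers,
        np.full(ncells, config.cells.A0_um2 / config.pixel_size_um**2),
        aspects,
        thetas,
        config.cells.contrast,
    )
    frames = []
    for i, z in enumerate(z_positions):
        sd = blur_per_z * abs(z - z_true)
        scene = gaussian_filter(base, sd) if sd > 0 else base.copy()
        frames.append(
            Frame(
                pixels=scene * vignette * dirt,
                timestamp_s=float(i),
                index=i,
                pixel_size_um=config.pixel_size_um,
            )
        )
    return ImageStack(frames=frames, provenance={"defocus_series": True})
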