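"""Image sharpness metrics and a two-stage autofocus search.

Two families of metrics are provided, both classic software-autofocus
measures: the Tenengrad (mean squared Sobel gradient magnitude) and the
intensity variance, optionally normalized by the squared mean so it becomes
invariant to illumination gain. Both are zero on a constant image and
invariant to additive intensity offsets; all values are unitless and only
comparable within one optical configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import convolve2d

from .errors import ShapeError
from .io import Frame

__all__ = [
    "FocusValue",
    "AutofocusResult",
    "tenengrad",
    "variance_metric",
    "score_frame",
    "autofocus",
    "METRICS",
]

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


@dataclass(frozen=True)
class FocusValue:
    value: float
    metric: str

    def __float__(self) -> float:
        return self.value


@dataclass
class AutofocusResult:
    best_position: float
    curve: list[tuple[float, FocusValue]]
    n_evaluations: int


def _pixels(frame) -> np.ndarray:
    return frame.pixels if isinstance(frame, Frame) else np.asarray(frame, dtype=float)


def tenengrad(frame, threshold: float = 0.0) -> FocusValue:
    """Mean of ``Gx^2 + Gy^2`` over interior pixels, 3x3 Sobel kernels.

    Borders where the kernel does not fully overlap the image are excluded.
    ``threshold`` discards gradient magnitudes below it before averaging
    (kept at 0 by default: the simplest form of the measure).
    """
    px = _pixels(frame)
    if px.shape[0] < 3 or px.shape[1] < 3:
        raise ShapeError(f"tenengrad needs at least 3x3 pixels, got {px.shape}")
    gx = convolve2d(px, _SOBEL_X, mode="valid")
    gy = convolve2d(px, _SOBEL_Y, mode="valid")
    g2 = gx**2 + gy**2
    if threshold > 0:
        g2 = np.where(g2 >= threshold**2, g2, 0.0)
    return FocusValue(value=float(g2.mean()), metric="tenengrad")


def variance_metric(frame, normalized: bool = False) -> FocusValue:
    """Population variance of the pixels; ``normalized`` divides by mean^2.

    The normalized form is invariant to multiplicative gain, which makes it
    robust to slow illumination fluctuations during a focus sweep.
    """
    px = _pixels(frame)
    if px.size == 0:
        raise ShapeError("variance_metric needs a nonempty frame")
    var = float(px.var())
    if not normalized:
        return FocusValue(value=var, metric="variance")
    mean = float(px.mean())
    if mean <= 0:
        raise ValueError(f"normalized variance requires mean > 0, got {mean}")
    return FocusValue(value=var / mean**2, metric="normalized_variance")


METRICS: dict[str, Callable] = {
    "tenengrad": tenengrad,
    "variance": lambda f: variance_metric(f, normalized=False),
    "normalized_variance": lambda f: variance_metric(f, normalized=True),
}


def score_frame(frame, metric: str = "tenengrad") -> FocusValue:
    """Score one frame with a named metric."""
    try:
        fn = METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown focus metric {metric!r}; choose from {sorted(METRICS)}")
    return fn(frame)


def _grid_argmax(
    provider: Callable[[float], object],
    positions: np.ndarray,
    metric_fn: Callable,
    curve: list,
) -> float:
    best_pos, best_val = None, -np.inf
    for p in positions:
        try:
            frame = provider(float(p))
        except Exception as exc:  # noqa: BLE001 - add position context
            raise RuntimeError(f"image provider failed at position {p}") from exc
        fv = metric_fn(frame)
        curve.append((float(p), fv))
        # strict > keeps the lowest position on ties (approach from one side)
        if fv.value > best_val:
            best_pos, best_val = float(p), fv.value
    return best_pos


def autofocus(
    image_provider: Callable[[float], object],
    search_range: tuple[float, float],
    coarse_step: float,
    fine_step: float,
    metric: str = "tenengrad",
) -> AutofocusResult:
    """Two-stage grid search for the sharpest stage position.

    A coarse grid over ``search_range`` is scored first, then a fine grid
    spanning one coarse step either side of the coarse optimum. The provider
    is called once per grid point; ties go to the lowest position.
    """
    lo, hi = search_range
    if not lo < hi:
        raise ValueError(f"search range must satisfy lo < hi, got ({lo}, {hi})")
    if not (0 < fine_step <= coarse_step):
        raise ValueError(
            f"need 0 < fine_step <= coarse_step, got fine={fine_step} coarse={coarse_step}"
        )
    metric_fn = METRICS.get(metric)
    if metric_fn is None:
        raise ValueError(f"unknown focus metric {metric!r}")

    curve: list[tuple[float, FocusValue]] = []
    coarse = np.arange(lo, hi + 0.5 * coarse_step, coarse_step)
    coarse_best = _grid_argmax(image_provider, coarse, metric_fn, curve)

    flo = max(lo, coarse_best - coarse_step)
    fhi = min(hi, coarse_best + coarse_step)
    fine = np.arange(flo, fhi + 0.5 * fine_step, fine_step)
    # skip positions already evaluated on the coarse grid
    seen = {round(p, 12) for p, _ in curve}
    fine = np.array([p for p in fine if round(float(p), 12) not in seen])
    fine_curve: list[tuple[float, FocusValue]] = []
    if len(fine):
        _grid_argmax(image_provider, fine, metric_fn, fine_curve)

    full = sorted(curve + fine_curve, key=lambda pv: pv[0])
    best_pos, best_val = full[0][0], full[0][1].value
    for p, fv in full:
        if fv.value > best_val:
            best_pos, best_val = p, fv.value
    return AutofocusResult(best_position=best_pos, curve=full, n_evaluations=len(full))
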