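"""Recover and compensate thermal stage drift from a simulated time-lapse.

A 3D-printed microscope stage expands during the incubator heat-up phase,
translating the field of view along an exponential-settle trajectory. This
example simulates such an acquisition, tracks the drift by cross-correlation
against frame 0, and compares the recovered track with the simulator's
ground truth.
"""

import numpy as np

from microlapse import (
    CellConfig,
    DriftConfig,
    SimConfig,
    apply_shifts,
    simulate_timelapse,
    summarize_drift,
    track_drift,
)

cfg = SimConfig(
    shape=(256, 256),
    n_frames=120,
    frame_interval_s=60.0,  # one frame per minute
    seed=1,
    drift=DriftConfig(S_inf=(15.0, -10.0), tau_s=1800.0, jitter_px=0.3),
    cells=CellConfig(motion_px_per_frame=0.0),
    dark_frames=None,
)
stack, truth = simulate_timelapse(cfg)

track = track_drift(stack, reference_index=0, subpixel=True)
true_rel = truth.true_shift - truth.true_shift[0]
rmse = np.sqrt(np.mean(np.sum((track.as_array() - true_rel) ** 2, axis=1)))

summary = summarize_drift(track, frame_interval_s=60.0, window=10)
aligned = apply_shifts(stack, track, fill=float(stack[0].pixels.mean()))
residual = track_drift(aligned, reference_index=0)

print(f"frames tracked          : {len(track)}")
print(f"total drift             : {summary.total_drift_px:.2f} px")
print(f"peak drift rate         : {summary.max_rate_px_per_frame:.3f} px/frame")
print(f"settle index            : {summary.settle_index}")
print(f"recovery RMSE vs truth  : {rmse:.3f} px   (sub-pixel tracking)")
print(f"residual after align    : {np.abs(residual.as_array()).max():.3f} px (max)")
# The RMSE shows how closely cross-correlation recovers the injected drift;
# the residual confirms the compensated stack is stationary to < 0.5 px.
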