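# microlapse

Processing toolbox for **long-term incubator time-lapse microscopy** on
low-cost, 3D-printed microscopes — the kind that sits inside a cell
incubator for a week taking one frame per minute while its printed stage
expands, its sensor collects dirt, and its illumination flickers.

The library turns such a raw image series into a drift-corrected,
shading-corrected, quality-screened stack, and quantifies the optics and the
biology on top of it:

- **Drift correction** — normalized circular cross-correlation against a
  settled reference frame, with 3-point parabolic sub-pixel refinement;
  fixed-feature ROI tracks (e.g. on sensor dirt) separate sensor motion from
  sample drift.
- **Quality control** — dark frames (mean < ½ × median mean) and corrupted
  frames (rolling-median robust z-score of frame max or sharpness) are
  flagged with recorded reasons and thresholds.
- **Flat-fielding** — the temporal stack mean, normalized to unit spatial
  mean, is the gain image: moving objects average out, vignetting and sensor
  dirt remain, and division removes both.
- **Software autofocus** — Tenengrad (mean squared Sobel gradient,
  `mean(Gx² + Gy²)`) and (normalized) intensity-variance sharpness metrics,
  plus a coarse-to-fine grid search.
- **Fourier ring correlation (FRC)** — effective resolution from the first
  crossing of `FRC(f) = Re Σ F₁F₂* / √(Σ|F₁|² Σ|F₂|²)` below the fixed 1/7
  threshold: `d = pixel_size / f_cutoff`.
- **Morphometry** — Otsu segmentation, ImageJ-style descriptors
  (`roundness = 4A/(π·major²)`, `circularity = 4πA/P²`) and per-time-bin
  whisker-plot percentiles of cell area.
- **Synthetic acquisitions** — a simulator that generates the full
  disturbance structure (exponential-settle thermal drift, vignetting,
  sensor dirt, dark/saturated frames, Poisson + read noise, Bayer sampling,
  growing motile cells) *with exact ground truth*, which is the test oracle
  for everything above.

## Worked example

Recover a 15 × (−10) px exponential-settle stage drift from a simulated
120-frame acquisition ([examples/drift_correction.py](examples/drift_correction.py)):

```
frames tracked          : 120
total drift             : 17.06 px
peak drift rate         : 1.319 px/frame
settle index            : 19
recovery RMSE vs truth  : 0.081 px   (sub-pixel tracking)
residual after align    : 0.033 px (max)
```

The tracker recovers the injected drift to below a tenth of a pixel, the
settle rule finds the end of the heat-up phase near frame 19 (analytically
≈ 21 for τ = 30 frames), and re-tracking the compensated stack confirms it
is stationary. The other scripts in `examples/` demonstrate quality
control, flat-fielding, autofocus, FRC resolution, cell-growth summaries
and the full pipeline (`microlapse run` on the command line); each prints
the numbers it computes and what they mean.

## Command line

Every stage is also a subcommand of the `microlapse` CLI:

```bash
microlapse simulate --seed 1 --outdir sim/          # synthetic acquisition
microlapse run --input sim/stack.tif --outdir out/  # full pipeline
microlapse frc stack.tif --pixel-size-um 0.5 --outdir frc/
```

`run` writes the aligned corrected TIFF, statistics CSV, QC report, gain
image, drift track and a manifest with configuration, frame accounting and
artifact checksums; identical seeds reproduce every artifact byte for byte.

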