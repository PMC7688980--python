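# Methods

This note documents the models and procedures implemented in `microlapse`,
the parameter choices that matter, what the synthetic-acquisition generator
does and does not emulate, and the numerical conventions.

## The processing problem

A low-cost microscope running unattended inside a cell incubator produces a
time-lapse with a characteristic disturbance structure: the 3D-printed
stage (ABS/PLA, thermal expansion coefficient of order 7 × 10⁻⁵/K) deforms
during the roughly one-hour heat-up phase, translating the field of view
along an exponential-settle trajectory; the sensor window carries dirt and
scratches and the optics vignette, both fixed in sensor coordinates;
illumination occasionally drops out (near-black frames) and the readout
occasionally saturates; and the sample itself — adherent, slowly growing,
motile cells — evolves over days. The pipeline recovers a clean, aligned,
shading-corrected series from this and quantifies focus quality, effective
resolution and cell morphology.

## Drift model and registration

Stage drift is modeled as `s(t) = S_inf · (1 − e^(−t/τ))` per component,
plus isotropic Gaussian per-frame jitter. Shift estimation computes the
normalized circular cross-correlation in the frequency domain on
mean-subtracted images; the integer argmax is refined per axis by a 3-point
parabolic fit of the correlation peak (clipped to ±0.5 px). The sign
convention throughout: a shift `(dy, dx)` means the moving frame appears
displaced down/right relative to the reference. A `peak_ratio` (highest to
second-highest peak outside a 3×3 neighborhood) flags unreliable estimates;
values near 1 mean the correlation surface is featureless.

Design choices:

- **Frequency-domain correlation** for O(N log N); mean subtraction removes
  the DC pedestal, optional raised-cosine apodization exists but is off by
  default (circular wrap effects are mild at the ≤ 20 px drifts involved).
- **Parabolic sub-pixel fit** rather than transform upsampling: adequate
  for the ≤ 0.5 px accuracy targeted, at negligible cost. Measured recovery
  error on the simulator at SNR ≈ 15 is < 0.1 px RMSE.
- **Reference-frame selection**: the acquisition drifts fastest during
  heat-up, so every frame is registered against one frame chosen *after*
  the drift has settled. The automatic rule smooths the provisional track
  (vs frame 0) with a rolling median over `window` frames — so sub-pixel
  jitter does not mask the drift rate — and returns the first index where
  the median per-frame increment stays below `tol_px` (default 0.3 px/frame)
  for a full window. If nothing settles, the start of the final window is
  used, with a warning. A manual override exists, mirroring the original
  manual practice.
- **ROI tracks** are computed on crops at identical sensor coordinates in
  reference and moving frames. An ROI on sensor dirt therefore reads ≈ (0,0)
  while the whole-frame track follows the sample; this separates camera/
  sensor motion from stage drift.
- **Compensation** translates each frame by minus its shift — exact integer
  translation by default (photometry-preserving), Fourier translation for
  fractional shifts — with vacated margins set to a fill value.
- QC-skipped frames inherit the previous valid shift rather than NaN, so
  compensation stays total.

## Quality control

Per-frame statistics are min, max, mean, and a sharpness metric. Two rules:

- **dark**: frame mean < `dark_factor` (default 0.5) × median frame mean.
  Scale-invariant and threshold-monotone.
- **corrupted**: robust z-score > `robust_z` (default 10) of the residual
  of frame max *or* sharpness from a rolling-median baseline
  (`detrend_window` = 9 frames, mirror padding). Dark frames are removed
  from the population first so dropouts cannot inflate the MAD.

Two calibration facts drive the defaults. First, on a multi-day series the
max and sharpness *trend* (drift carries bright objects across the vignette
and dirt; cells grow), so deviation must be measured from local context —
a global median/MAD screen misfires in bursts wherever the trend steps.
Second, the maximum of a shot-noise-limited image is an extreme-value
(Gumbel-tailed) statistic: its residuals exceed 5 robust standard
deviations a few percent of the time on perfectly healthy frames, while
genuine corruption (saturation at full scale, garbage readout) sits at
z ≈ 10³. The threshold of 10 is therefore still enormously conservative
with respect to real corruption but keeps the healthy-frame false-flag
probability well below 1%. Measured on the simulator across 40 seeds:
dark and saturated sensitivity 1.0, false positives ≈ 0.35%. All
thresholds are recorded in the QC report.

## Flat-fielding

The gain image is the pixelwise temporal mean of the (background-
subtracted) stack, clamped at 10⁻⁶ of its maximum and normalized to unit
spatial mean; correction is `(frame − background)/gain`. Background is a
scalar low percentile (q = 1) of the QC-passing stack by default; a
dark-frame map is supported. Corrected values are not clipped — linearity
matters more than cosmetics, and integer export clips anyway.

The estimate rests on moving objects averaging out of the temporal mean.
Both the gain and the drift track are computed in **raw sensor
coordinates**: vignetting and dirt are fixed to the sensor, so aligning
first would smear them (a regression test asserts this), and the dirt ROIs
only exist before correction removes them. Corrections are applied after
tracking, then shifts are applied.

Known limitation: cells that barely move relative to the stack length are
absorbed into the gain and divided out of the corrected frames. On real
week-long acquisitions the averaging assumption holds; on short synthetic
stacks with near-static cells it does not, which is why gain-recovery
accuracy is assessed on blank scenes (0.3–0.4% RMS at SNR ≈ 40) and with
fast-moving dim cells (< 2% RMS over 300 frames), and why the pipeline
offers `ff_coords="none"` (alignment-only) for data where shading
correction is not wanted. For the same reason, strict end-to-end
idempotence (re-running the pipeline on its own corrected output) holds in
alignment-only mode; with correction on, the residual gain contamination is
sensor-fixed while the scene is aligned, and the two cannot both be
stationary.

## Focus metrics and autofocus

Tenengrad is the mean over interior pixels of `Gx² + Gy²` with the 3×3
Sobel kernels; mean (not sum) aggregation makes values comparable across
frame sizes, and an optional gradient threshold exists but defaults to 0
(the simplest form). The variance metric is the population variance,
optionally divided by the squared mean (gain-invariant). Both are zero on
constant images and invariant to additive offsets; values are unitless and
not calibrated to physical defocus.

The autofocus search is a two-stage grid: score a coarse grid over the
range, then a fine grid spanning ± one coarse step around the coarse
optimum; ties go to the lowest position (deterministic, and matches
hardware practice of approaching focus from one side). The search strategy
and step sizes are this package's choice — any unimodal sharpness curve
works.

## Fourier ring correlation

`FRC(r) = Re[Σ_ring F₁·conj(F₂)] / √(Σ_ring|F₁|² · Σ_ring|F₂|²)` over
concentric rings one Fourier pixel wide (configurable), DC excluded, ring
centers at `(k + ½)/N`. Inputs are mean-subtracted and Tukey-windowed
(α = 0.25) by default to suppress edge-discontinuity leakage; the window is
recorded in curve and result. Resolution is the linear interpolation of the
first crossing below the fixed 1/7 threshold, `d = pixel_size/f_cutoff`;
curves that never cross are reported unresolved at the Nyquist-limited
bound `2 × pixel_size`. σ-based threshold curves are not implemented. An
even/odd frame split turns a single aligned series into an FRC pair.

Numerical notes: on *circularly periodic* synthetic fixtures the window
should be disabled — there is no edge discontinuity to suppress, and the
band-edge leakage the window itself introduces biases a sharp-cutoff
estimate upward by ~10–15%. For whole-curve noise summaries, averaging
|FRC| with rings weighted by their Fourier-sample count is the meaningful
statistic; the innermost rings hold ~10 samples and contribute pure
estimator variance (per-ring sd ≈ 1/√n).

## Morphometry

Segmentation is global Otsu thresholding (bright or dark polarity) with
8-connected components and a minimum-area filter — deliberately simple,
intended for well-contrasted cells on shading-corrected frames. Measures
follow the Fiji/ImageJ conventions: area = pixel count × pixel_size²,
perimeter by boundary-step weighting, axes from second central moments,
`roundness = 4A/(π·major²)` and `circularity = 4πA/P²` (both may exceed 1
by a few percent through digitization; not clipped). No tracking: cells are
pooled per time bin and summarized by linear-interpolation percentiles
(10/25/50/75/90), the whisker-plot convention. Empty bins are skipped with
a warning.

## The synthetic-acquisition generator

The simulator renders, per frame: background + soft-edged elliptical cells
at drifted positions, multiplied by the sensor-fixed vignette and dirt
gains, optionally defocus-blurred, Poisson-sampled at `photons_per_unit`
and read-noised, Bayer-sampled on request. Dark frames scale the clean
scene by 0.05 (dropout, statistics stay finite); corrupted frames are
overwritten with the saturation level. All randomness derives from one
seed through independent sub-streams per disturbance, so toggling one
never changes another's realization and identical configurations are
bit-identical.

Defaults are chosen as a realistic reduced-scale incubator acquisition:
256×256 px at 1 µm/px, 100 frames at 1 frame/min, drift asymptote ≈ 20 px
with τ = 1 h and 0.3 px jitter, 30% corner vignetting, five dirt spots of
4–10 px radius at 50% attenuation with ~3 px defocused rims (dirt sits on a
cover window above the sensor plane, so its shadow is soft), 15 cells of
200 µm² growing 2%/hour with a 0.5 px/frame random walk and contrast 100
over background 10, shot noise at 2 photons/unit plus read σ = 3 (cell SNR
≈ 12–15), 5% dark-frame probability. Cells are placed with a minimum
pairwise separation (2.4 × the maximal semi-axis) and their walks reflect
at the field margins: adherent cells spread side by side rather than
stacking, and they do not leave the dish.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: optical PSFs beyond Gaussian blur, photobleaching,
cell division/death/shape dynamics, spatially structured backgrounds,
rolling-shutter or compression artifacts, and focus drift coupled to lateral
drift. Cell geometry is a smooth ellipse, so segmentation accuracy on real
textured cells will be worse than the simulator suggests.

Rendering detail: cells are drawn analytically at sub-pixel positions (a
`tanh` radial profile whose half-maximum contour encloses exactly the
ground-truth area), rather than by shifting a rasterized layer — the
sensor-fixed gains still never move, which is what makes the dirt-ROI
separation testable, but cell geometry is exact at any sub-pixel offset.

## Pipeline, determinism, formats

Stage order: read → green extraction (Bayer mean of the two G sites per
2×2 tile at half resolution, no demosaicing; RGB takes the G plane) →
mean-binning (trailing rows/columns cropped, never padded; pixel size
scales) → preview export → statistics → QC → background + gain estimation
(raw coordinates) → reference selection → tracking (raw coordinates, whole
frame + ROIs) → flat-field application → shift application → aligned stack
mean → drift summary. Green extraction precedes binning as a fixed
convention. The manifest records the configuration, package version, frame
accounting (read = kept + excluded), warnings, and SHA-256 checksums of all
artifacts; identical config + seed reproduce identical CSV/JSON artifacts.

I/O: multi-page TIFF or directories of TIFF/PNG/JPEG (natural filename
sort, ties lexicographic), 16-bit TIFF round trips losslessly, previews are
8-bit PNGs, tables CSV, reports JSON. Raw Bayer data is accepted as
already-extracted mosaics in TIFF with a declared pattern — vendor-specific
raw-in-EXIF encodings are out of scope. Coordinates are row-major (row,
col), origin top-left, 0-based.

## Benchmark problem sizes

The bundled benchmarks use: 200 frames of 256² for drift recovery; 20 × 100
frames of 128² for QC; 60 frames of 128² blank scenes for flat-fielding
(split-half: gain from even frames applied to odd frames, so the CV
reduction is not a trivial x/x identity); an 11-step defocus series; 256²
FRC fixtures; 60 frames of 256² with 15 growing cells for morphometry
(corrected with the ground-truth gain — flat-field estimation accuracy is
benchmarked separately on the blank scenes, see the limitation above); 100
random 32² fixtures against the brute-force correlation oracle; and a
double 100-frame pipeline run for determinism. These sizes reproduce the
study conditions at a scale where the whole suite runs in well under a
minute on one CPU.
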