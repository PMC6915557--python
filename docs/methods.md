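# Methods

## Problem setting

Fluorescence images of platelet aggregates on an endothelialized
microfluidic channel have a strongly skewed, unimodal intensity histogram:
a tall, narrow background peak (unbound label, camera offset and read
noise, dim endothelial autofluorescence) and a long, sparse tail of bright
aggregate pixels. Bimodal methods such as Otsu assume two comparable modes
and misplace the threshold on such data; the triangle construction instead
finds the "base" of the single peak and is therefore the method of choice
for sparse bright-on-dark fluorescence.

## Rotation correction

Coordinates are 0-based, row-major; intervals are half-open. The
misalignment angle α is positive when the channel's top wall descends from
left to right (rows grow downward). Manual estimation takes the two
(row, col) points where the top wall crosses the left and right image
borders and computes α = atan(Δrow/Δcol). Automatic estimation:

* Each column is smoothed with a 5-pixel moving average and scanned top to
  bottom for the first row r with I(r−1) < I(r) ≥ I(r+1) whose value
  exceeds a noise floor (background mean + 2 SD). The floor is estimated
  from the raw pixels of the top ten rows, pooled over all columns and
  excluding exact zeros so that the zero-filled corner wedges of an
  already-rotated raster cannot bias it.
* A sweep over a uniform angle grid (default ±5° in 0.05° steps) rotates
  the image, recomputes the per-column wall rows, and scores each candidate
  by the variance of those rows; the wall is flat — variance minimal —
  exactly when the rotation cancels the misalignment. Columns inside the
  worst-case corner-wedge margin (`ceil(tan(range)·n_rows)` pixels at each
  border) are excluded from the score for every candidate alike, because
  rotation fill makes their wall pixels unreliable.
* The correction itself is a bilinear rotation by α about the raster
  centre, clipped to the valid intensity range; α = 0 short-circuits to a
  bit-exact copy. Exposed corners are filled with 0; ROI #2 excludes image
  borders by construction, so fill never enters any quantified statistic
  for |α| ≤ 5° at the default frame sizes.

On synthetic fixtures the sweep recovers angles in ±3° to within one sweep
step (0.05°), well inside the ±0.1° tolerance used in the acceptance tests.

## Regions of interest

ROI #1 spans rows [top wall, top wall + channel width) over all columns;
the channel width (default 300 µm) comes from the device geometry rather
than from detecting the bottom wall. ROI #2 shrinks ROI #1 by
`ceil(rim/pixel_size)` pixels at top, bottom, left and right (default rim
50 µm). Whether the wall lines themselves belong to ROI #1 is a
convention; we include the full band from the top-wall row. ROI #1 is used
only for threshold estimation, so including the bright wall pixels adds a
fixed, far-tail contribution that does not move the threshold (the
triangle lands at the background-peak bend, far below wall intensity).

## Triangle threshold

With the histogram of ROI #1 (uniform bins over [0, 2^bit_depth); default
256 bins for 8-bit and 1024 for 16-bit data):

1. Peak bin = argmax of counts (first maximum on ties).
2. Artificial zero = first bin above the peak with count < 0.01 % of the
   maximum count; if none exists, the last bin.
3. Crop to [peak, zero]; map bin index span and counts/max to [0, 1]².
   Normalization makes the construction invariant to histogram scale,
   which the purely geometric description otherwise is not.
4. Hypotenuse from (0, 1) to (1, counts[zero]/max); per-bin orthogonal
   point-to-segment distances; threshold bin = argmax of distance, peak
   excluded, ties broken toward the lower bin (distances are quantized at
   1e-12 so exact geometric ties — e.g. a perfectly linear ramp — are not
   decided by floating-point dust). The threshold value is the lower edge
   of the threshold bin, and foreground is *strictly above* it: the
   threshold bin sits at the base of the background peak and its own
   pixels are background-like.

### Empty-signal guard

If an image contains no aggregates at all, the construction would place
the threshold inside the background peak and report a grossly exaggerated
coverage. The guard compares the right tail span (peak → artificial zero)
with the left span of the peak at the same 0.01 % cutoff. Any roughly
symmetric background gives a ratio near 1 *independent of its width* —
including after interpolation has narrowed the noise distribution — while
genuine foreground stretches the right side fifteen-fold or more. Below a
ratio of 3 the triangle raises `EmptySignalError`; the pipeline then
reports zero coverage with a `degenerate` flag, which is the correct call
for an image with no detectable signal anywhere in ROI #1. The guard can
be disabled (`min_tail_ratio=0`) for analysing the bare construction.

### Two-ROI transfer

Estimating on ROI #1 and applying to ROI #2 is what makes the scheme
robust on healthy endothelium: edge effects concentrate aggregates in the
50 µm rim, inside ROI #1 but outside ROI #2, so the histogram tail is
populated even when the quantified region is clean. The rim-only fixture
exercises exactly this: the transferred threshold yields ≈ 0.02 % ROI #2
coverage, while thresholding ROI #2 alone trips the guard.

## Quantification

Coverage is reported as 100·white/(white+black) by default; the
alternative convention 100·white/black is exposed as a switch because the
two diverge at high coverage (at a few percent coverage they differ by
under 0.15 percentage points). Connected components use 8-connectivity by
default, matching the regionprops convention of the original MATLAB-style
workflow; per-component records carry pixel and µm² areas, centroid,
bounding box and equivalent diameter. No minimum-size filter is applied by
default — slightly out-of-focus granular signal is real platelet signal
and belongs in coverage — but `min_area_um2` is available. The default
size-distribution bins are logarithmic, ten per decade from 1 to 10⁴ µm².

## Validation statistics

Pixel-wise confusion counts treat the manual (or synthetic ground-truth)
mask as reference; multi-image metrics are micro-averaged (counts summed
before percentages), equivalent to superimposing all masks. Coverage
agreement is summarized by R² = 1 − Σ(tᵢ−mᵢ)²/Σ(tᵢ−t̄)², with residuals
against the identity line and variance about the triangle-axis mean; the
statistic can be negative when agreement is worse than predicting the
mean. Freeform manual outlines can be rasterized to masks by even-odd
polygon filling.

## Duct hemodynamics

For fully developed, incompressible laminar flow in a rectangular duct
(width w ≥ height h, no-slip walls), the bottom-wall shear rate at lateral
position y is

γ(y) = (4Gh/π²μ) Σ_{n odd} n⁻² [1 − cosh(nπ(y−w/2)/h)/cosh(nπw/2h)],

with G the pressure gradient, scaled so the velocity integral equals the
prescribed Q (the classic tanh-series flow factor). Numerics: the
odd-harmonic constant Σn⁻² = π²/8 is substituted in closed form, so the
truncation error of the remaining exponentially decaying sum is negligible
from a few dozen terms (default 200; the 200→400 change at the centreline
is < 10⁻⁴ relative). The cosh ratio is evaluated as
exp(a−b)(1+e^{−2a})/(1+e^{−2b}) to avoid overflow, and side-wall positions
return the analytic limit 0 exactly. In the parallel-plate limit w ≫ h the
centreline value recovers γ = 6Q/(w·h²) to < 1 %.

For the 300 µm × 51 µm device at the 7.8 µL/min flow that produces
1000 s⁻¹, the shear at 50 µm from either side wall is 96.3 % of the
centreline maximum — the quantitative justification for the ROI #2 inset.
The model assumes fully developed Newtonian flow; entrance effects and
blood rheology are outside its scope, so the rim percentage is an
approximation to what a 3-D simulation of a finite channel section would
give.

## Synthetic fixtures

The generator renders, per seed: Gaussian background (default mean 20,
SD 2.5 counts on the 8-bit scale — a quiet dark-field camera background),
a channel band 6 counts brighter than the exterior, two 3-pixel wall lines
at 230 counts, and non-overlapping elliptical aggregates at 180 ± 10
counts with areas log-uniform in a configurable range. Aggregate edges are
softened with a 0.5 px Gaussian blur — a mild defocus consistent with a
~1 µm pixel at 10× — applied after the crisp ground-truth mask is
captured, so the expected segmentation halo (≈ 1 boundary pixel per
aggregate) is part of the tolerance budget rather than of the truth.

Misalignment is rendered *analytically in the rotated frame* (tilted wall
lines, rotated ellipse centres and orientations) rather than by resampling
an aligned rendering: a real misaligned micrograph is sampled by the
camera directly, with stationary noise and clean edges, whereas resampling
sharpens the histogram noise peak and leaves zero-filled corners — imaging
artifacts the study conditions should not contain. Ground truth is
rasterized in both the rotated frame (matching the image) and the aligned
frame (matching an ideally corrected image).

The 10-image validation suite mixes "untreated" fixtures (0–5 aggregates
of 25–64 µm², ground-truth ROI #2 coverage well below 0.2 %) and
"activated" fixtures (25–50 aggregates of 300–3000 µm², coverage roughly
8–28 %), each with a random misalignment in ±3°. Untreated images
routinely trip the empty-signal guard — by design: their ROI #1 tail is a
handful of pixels — and the reported zero coverage is then within the
sparse-image tolerance of the truth. At least 25 activated aggregates keep
the blur pedestal above the artificial-zero cutoff in every histogram bin,
so the tail always bridges to the aggregate intensities.

What the fixtures do **not** emulate: Poisson (signal-dependent) noise,
fibrin strands, red/white blood cells, endothelial background drift over
time, uneven illumination, and out-of-plane aggregate structure. Passing
the synthetic acceptance suite therefore demonstrates the correctness of
the geometry, threshold and bookkeeping chain under controlled conditions,
not performance on every pathology of real data.

## Known limitations

* The triangle threshold lands at the bend of the background peak
  (≈ 2.5–3 noise SD above the mean); a heavy-tailed background would
  inflate coverage on nearly-clean images. The guard catches the fully
  signal-free case but not intermediate background pathologies.
* Wall detection assumes the top wall is the first bright feature from the
  top of the frame; debris above the channel would defeat it.
* Channel width is taken from the device geometry, not measured; curved or
  tapered channels are out of scope.
* Validation is strictly pixel-wise; no object-level matching or
  inter-rater modelling.
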