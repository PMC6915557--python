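# plateletquant

Automated quantification of platelet aggregation in endothelialized
microfluidic channels from single-channel fluorescence microscopy images.

When whole blood is perfused through an endothelium-lined microfluidic
channel, fluorescently labelled platelets adhere and form aggregates.
Quantifying how much of the channel they cover — and how large the
aggregates are — usually involves manual thresholding or manual outlining,
which is slow and operator-dependent. `plateletquant` automates the whole
chain for researchers running thrombosis-on-a-chip and
vasculature-on-a-chip experiments:

1. **Rotation correction** — the misalignment angle α of the channel on the
   microscope stage is estimated either from two manually indicated
   top-wall/border intersections (arctangent of Δrow/Δcol) or automatically,
   by scanning each image column top-to-bottom for its first local intensity
   maximum (the top wall) and sweeping candidate angles to minimize the
   variance of the per-column wall rows.
2. **Dual ROI construction** — ROI #1 spans the full channel band; ROI #2 is
   inset 50 µm from both channel walls and both image borders.
3. **Triangle thresholding** — on the ROI #1 intensity histogram, an
   *artificial zero* is set at the first bin beyond the peak whose count
   falls below 0.01 % of the maximum count. The histogram is cropped to
   [peak, zero] and normalized to the unit square; the *hypotenuse* runs
   from the peak (0, 1) to the artificial zero (1, c_z/c_max); the
   threshold is the bin with the greatest orthogonal distance to the
   hypotenuse. The threshold is estimated on ROI #1 but applied to ROI #2:
   aggregates accumulating in the low-shear near-wall rim keep the
   histogram tail populated even when the channel interior is clean, so the
   method never degenerates into splitting the background peak.
4. **Quantification** — platelet coverage (white/total or white/black, both
   exposed) and the aggregate size distribution via connected-component
   analysis (8-connectivity by default).
5. **Validation** — pixel-wise confusion metrics (sensitivity, specificity,
   accuracy) against manual or ground-truth masks, and the R² of coverage
   scatter measured against the identity line y = x.
6. **Hemodynamics** — the parallel-plate relation γ = 6Q/(w·h²) and the
   exact Fourier-series wall-shear profile of a rectangular duct, which
   shows that 50 µm from the side walls the shear has recovered to ≥ 95 %
   of the centreline value — the rationale for the ROI #2 inset.

A seeded synthetic-image generator (`plateletquant.synthetic`) renders
channels with known wall geometry, misalignment angle and aggregate ground
truth, so the entire pipeline is testable without microscopy data.

## Worked example

```python
from plateletquant import FixtureSpec, generate, analyze

fx = generate(FixtureSpec(seed=7, true_alpha_deg=2.0))   # synthetic channel
res = analyze(fx.image)                                  # full pipeline

print(f"misalignment: {res.geometry.alpha_deg:+.2f} deg")
print(f"triangle threshold: {res.triangle.threshold_value:.0f} counts")
print(f"platelet coverage in ROI2: {res.coverage.coverage_pct:.2f}%")
print(f"aggregates detected: {len(res.aggregates)}")
```

prints

```
misalignment: +2.00 deg
triangle threshold: 32 counts
platelet coverage in ROI2: 12.87%
aggregates detected: 55
```

The fixture was generated with a true misalignment of +2.00° and a
ground-truth ROI #2 coverage of 11.59 %: the sweep recovers the angle
exactly, and the measured coverage sits within the expected halo bias of
the blurred aggregate edges (each blob is detected with roughly one extra
boundary pixel). The threshold of 32 counts sits just above the background
peak (mean ≈ 26 counts) and far below the aggregate intensity (≈ 180).

The same pipeline is available from the shell:

```bash
plateletquant analyze image.tif --pixel-size 1.0 --out-dir results/
plateletquant compare triangle_mask.png manual_mask.png
plateletquant shear --gamma 1000 --width-um 300 --height-um 51
plateletquant simulate --seed 1 --n 10 --out-dir fixtures/
```

`plateletquant shear --gamma 1000` prints

```
Q = 7.803 uL/min for gamma = 1000 1/s
shear at 50 um from the side walls: 96.29% of the centerline value (1119.8 1/s)
```

i.e. perfusing at ≈ 7.8 µL/min produces an arterial wall shear rate of
1000 s⁻¹ in a 300 µm × 51 µm channel, and everywhere inside the 50 µm rim
the local wall shear is at least 96 % of the centreline maximum.

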