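# Methods

## Measurement model

A transparent microstructure filled with an absorbing dye and scanned in
transmission mode produces, at each pixel, a transmitted count `It` out of
an incident count `I0` (both 16-bit grayscale, 0–65535). Absorbance is
`A = log10(I0/It)` — base 10 throughout, which is the Beer–Lambert
convention consistent with an extinction coefficient of order
5×10⁻⁴ mM⁻¹μm⁻¹ for Allura Red in the blue channel. Under Beer–Lambert,
`A = ε·c·d` with ε the extinction coefficient (mM⁻¹μm⁻¹), c the dye
concentration (mM) and d the optical path length (μm). Inversion is
pixelwise: `d = A/(ε·c)`.

Assumptions:

- **One flat bounding surface.** The reconstructed `d` equals the
  structure depth only when the opposite surface is flat. For laminated
  chambers where both floor and ceiling deform, `d` is the *sum* of both
  deformations; the surface rendering is then advisory but integrated
  volumes remain correct, since volume only needs total optical path.
- **Linear regime.** Calibration and quantification assume `A ≲ 0.6`.
  `recommend_concentration(d_max, ε, A_max=0.6)` returns
  `c = A_max/(ε·d_max)`, the concentration placing the deepest feature at
  the bound: deep chambers get dilute dye (160 μm → 7.2 mM, so 6 mM is a
  comfortable choice at A = 0.4992), shallow wells get concentrated dye
  (10 μm → 115 mM, hence ~48 mM in practice).
- **Linear sensor response.** No gamma/tone curve is applied in the
  forward model (film-scan mode is treated as radiometrically linear); an
  optional `gamma` parameter exists for realism studies only.

## Calibration

`ExtinctionCalibrator` fits an ordinary least-squares line of mean
absorbance on the independent variable of a standard series — six depths
(7.9–160 μm) at fixed 6 mM, or six concentrations (1.5–48 mM) at fixed
27 μm — and derives `ε = slope / fixed_value`. The intercept is left free
and reported as a QC diagnostic (a large intercept signals reference
mismatch or stray light); the fit form with a forced zero intercept was
deliberately not used, since it hides exactly that failure mode. Replicate
sds are retained and can drive an optional weighted fit; the default is
unweighted on per-point means. Fits from both series modes may be pooled
by inverse-variance weighting of ε (`combine_fits`); bilinearity of
Beer–Lambert guarantees both modes estimate the same ε, and the noiseless
round-trip test recovers it to four significant figures. Blue is the
default channel (largest ε, best linearity for a red dye); other channels
are allowed with a warning.

## Forward model (synthetic scans)

`render_depth_field` rasterizes analytic features at pixel centers
(x right, y down, pixel (row, col) centered at ((col+0.5)p, (row+0.5)p),
pitch p = 25400/dpi μm). No area-weighted anti-aliasing is applied at
edges — a pixel is in or out by its center — which keeps rendered volumes
exactly interpretable and testable against closed forms:

- cylinder: `πr²d`;
- isotropic-etch basin well (flat bottom of mask radius r₀, quarter-circle
  sidewall of radius d): `π[r₀²d + (π/2)r₀d² + (2/3)d³]`;
- cone well: `πr²d/3`;
- Gaussian ablated channel of sigma w and half-length L: `√(2π)·d·w·2L`;
- sagging chamber: cylinder minus a spherical cap whose volume is
  `k_sag·r³` (k_sag dimensionless, default 0.05). Only the cubic *scaling*
  of the sag volume is physically constrained; the spherical-cap *shape*
  is this package's modeling choice, with the cap height solved from the
  cubic `πh(3r²+h²)/6 = k_sag·r³`. The cubic-vs-quadratic competition
  reproduces the characteristic behavior that fractional volume deficit
  `k_sag·r/(πd)` grows linearly with chamber radius.

`simulate_scan` computes `It = I0·10^(−ε_x·c·d)` per channel
(ε_B ≥ ε_G ≥ ε_R, defaults 0.00052/0.00026/0 mM⁻¹μm⁻¹ emulating Allura
Red's blue-heavy absorption and dye-blind red channel), adds Gaussian
sensor noise (default sd 100 counts; optional Poisson shot noise), then
rounds and clips to [0, 65535]. Noise is additive on transmitted counts
because the scanner's noise model is not otherwise constrained; 100
counts on a 60,000-count background makes single-scan depth noise clearly
visible at 12800 dpi, matching the qualitative need for multi-scan
averaging. Identical seed + config gives bit-identical images; distinct
seeds model repeat scans.

What the simulator does *not* emulate: optical blur (scanner MTF),
refraction at curved walls, illumination non-uniformity, registration
drift between repeat scans, dye fouling. Passing round-trip tests
therefore validate the inversion arithmetic, segmentation and statistics,
not the optics of a physical scanner; on real hardware, edge sharpness
and absolute accuracy are limited by effects outside this model.

## Averaging and noise

Absorbance maps from N repeat scans are averaged pixelwise;
with i.i.d. sensor noise the residual RMS falls as 1/√N (verified by
Monte-Carlo at N = 4 and 9 within ±20%). Repeat flatbed scans are assumed
pixel-aligned (`align="none"` default); an integer-shift registration by
maximum cross-correlation is available as a safety option. Zero
transmitted counts are clamped to 1 and masked invalid rather than
producing infinities, preserving area statistics. Negative reconstructed
depths (noise on blank regions) are *kept*, so blank-region statistics
stay unbiased; clipping is a report-time choice.

## Morphometry definitions

- **Segmentation**: connected components (8-connectivity) of pixels with
  depth ≥ threshold; threshold defaults to an Otsu split of the depth
  histogram, minimum region area defaults to 10 pixels. Touching wells
  merge — by design; the array generators keep spacing ≥ 1.5 diameters.
  Labels are assigned in row-major centroid order, so output is
  deterministic.
- **Volume**: `Σ depth · p²` over the region's thresholded pixels,
  reported in nL (1 nL = 10⁶ μm³). Sub-threshold rim pixels are excluded;
  the ≥99% total-volume recovery property on noiseless arrays bounds the
  rim loss, and the threshold is configurable where it matters.
- **Half-depth area**: area of region pixels with depth ≥ ½ × the region
  maximum, the maximum taken after 3×3 median smoothing (a raw maximum is
  biased upward by noise). For flat-bottomed wells this equals the full
  area; for an ideal cone it is ¼ of the mouth area. Known bias: on a
  *pointed* noiseless cone the median filter slightly lowers the apex
  reference, inflating the half-depth area by a few percent at ~50-pixel
  feature radius; `smooth=False` gives the exact geometric value.
- **Cross-sections**: bilinear sampling along an arbitrary line at
  pitch spacing. Longitudinal profiling takes `n_slices` perpendicular
  slices at the midpoints of equal axis segments and reports the
  pointwise mean and ±1 sd envelope; wall-position jitter appears as sd
  peaks at the walls with a quiet floor.

## Population statistics and typing

`summarize` reports the sample mean, sample sd (n−1) and
CoV = 100·σ/μ; report tables round CoV to 2 significant figures. Note on
source tables this package's tests reproduce: the per-array spread rows
are labeled "variance" there but carry nL units and satisfy
CoV = sd/mean (0.0013/0.0880 = 1.5%), so they are treated as standard
deviations; reports here say "sd".

`WellTypeClassifier` runs Lloyd's K-means (k-means++ initialization, best
of 10 restarts by within-cluster sum of squares, seeded) on z-scored
features. Standardization is essential because volume (nL, ~0.1) and
half-depth area (μm², ~10³) differ by four orders of magnitude; without
it the area axis alone would drive clustering. With volumes only, the
classifier runs on the 1-D feature. Cluster ids are arbitrary, so
accuracy against designed types uses the permutation minimizing
disagreement (Hungarian assignment on the confusion matrix), verified
against brute-force enumeration of all k! mappings on small instances.
Outlier wells are flagged at |z| > 3 per cluster when labels exist —
otherwise a minority well type would be flagged wholesale.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for quick, deterministic runs on
one CPU: rendered fields of tens to hundreds of wells at 2–21 μm pitch
for geometry and round-trip checks, and the full 10,000-well three-type
design via the statistical volume surrogate (`sample_well_volumes`:
per-group Gaussians at the designed means, negative draws redrawn and
logged) for typing accuracy. The three designed groups sit ~11 group-sds
apart, so misclassification is dominated by the 6-σ midpoint tails and is
essentially zero — comfortably within the ≤22-of-10,000 reference level.
Other numerics: depth-discretization keeps rendered cylinder volumes
within 1% of `πr²d` for r/p ≥ 20; noiseless forward–inverse round trips
agree to ≲0.05% per pixel (16-bit quantization is the floor, well under
the 0.5% working tolerance at counts ≥ 10); K-means determinism comes
from the seed plus restart-best selection; Shapiro normality diagnostics
subsample to ≤5000 values and are advisory only.

## Limitations

- No sub-pixel edge localization; feature boundaries are thresholded
  pixel sets, so very small wells (radius ≲ 10 px) carry percent-level
  volume discretization error.
- Merged (touching) features are not split (no watershed).
- The scanner bed is assumed flat and the illumination uniform; no
  field-flatness or tilt correction.
- Equal-cardinality label sets are required for misclassification
  counting; empty predicted clusters raise rather than being padded.
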