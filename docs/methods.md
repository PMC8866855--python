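# Methods

## Scope and model

`gliamorph` quantifies myeloid-cell activation in two-channel confocal
volumes (channel 0 = Tmem119 marker, channel 1 = Iba1 segmentation
channel). The analysis assumes cells are resolvable in a maximum
z-projection, are separable by a single global gray-level threshold on
the preprocessed Iba1 channel, and do not need splitting of touching
cells (no watershed); the synthetic generator produces scenes consistent
with these assumptions.

## Image chain

Order is fixed: max projection → channel split → (Iba1 only) rolling-ball
background subtraction → mean smoothing → unsharp mask → constant
threshold → 8-connected components → debris and border filtering. The
marker channel receives only a small-radius rolling-ball subtraction
before intensity measurement; marker means are always taken on that
image, never on the Iba1-chain output.

**Rolling ball.** The background is a grayscale opening with a non-flat
ball structuring element (`scipy.ndimage` erosion/dilation with the ball
height profile); subtraction clips at 0, so a constant image maps to
zero. Radii are in pixels (50 for Iba1, 20 for the marker, both
configurable). For radii above 16 px the image is shrunk by a
block-minimum (factor 2/4/8 by radius), the opening run at reduced
radius, and the background bilinearly re-enlarged and capped at the
image — the standard speedup for this filter; small radii run exact, and
the exact path is what the brute-force oracle in the tests checks.
Note that a 20 px ball (4 µm at 0.2 µm/px) fits under somata wider than
~8 µm, so part of the soma plateau of large cells is treated as
background; this is a property of the prescribed radius, reported as-is.

**Smoothing and unsharp.** Smoothing is one pass of a 3×3 uniform mean
filter, reflective borders. Unsharp masking is
`(I − w·G_σ(I)) / (1 − w)` with σ = 2 px and w = 0.6 by default,
negatives clipped; constants are preserved exactly.

**Threshold.** The cut-off is a required, global constant (the
segmentation contract is "one threshold per comparison"). A helper
derives one as a high quantile (default 0.99; 0.999 used in the examples)
of a preprocessed control image. Components smaller than 20 µm² are
discarded as debris; components touching the window border are excluded
by default.

## Morphometry

Area is pixel count × (pixel size)². Perimeter is the length of the
sub-pixel boundary polygon traced at the half level (marching squares)
after one pass of (1, 2, 1)/4 vertex relaxation. The relaxation removes
the staircase bias that makes raw digital boundaries ~5 % too long: a
digitized disk of radius 50 px measures circularity 0.976 (raw polygon:
0.907), and a 20 px square measures 0.828 against the analytic π/4 ≈
0.785. Circularity is clipped at 1.0 because very small digitized disks
otherwise exceed it. A 4-direction Crofton estimator is available behind
`perimeter_estimator="crofton"` for sensitivity checks; values near the
0.16 gate are estimator-sensitive, which is why the estimator is fixed
and documented.

Class gates: hypertrophic iff area ≥ 250 µm² (the boundary value is
assigned to hypertrophic so the gates partition the plane); else ameboid
iff circularity > 0.16; else ramified. The putative-infiltrated flag is
set iff circularity > 0.5, independently of class — in practice only
small round cells reach such values, and the flag marks them as likely
blood-borne myeloid cells rather than forming a fourth class.

## Marker quantification

Per cell: mean gray over the footprint; soma obtained by opening the
footprint with a 2 µm disk (process half-widths are ≤ 1 µm, somata
≥ 5 µm, so the disk fits only in the soma) and keeping the largest
remnant; ramification signal reported two ways. The direct mean over
footprint-minus-soma pixels is primary because it satisfies the exact
pixel-weighted reconstruction
`n_soma·mean_soma + n_ram·mean_ram = n_total·mean_total`; the literal
difference `mean_total − mean_soma` is reported alongside as
`ramification_literal`. Cells whose soma vanishes under the opening
(thin debris) are flagged and report soma fields as NaN.

ROI windows are axis-aligned squares anchored at a lesion-edge point and
offset along a unit direction (0/350/700 µm in the motivating design);
cell membership is by footprint centroid, so adjacent windows never
double-count a cell.

## Synthetic scenes

The generator emulates 210 × 210 × 12 µm acquisitions at 0.2 µm/px and
1.13 µm z-steps (11 slices), 12-bit range. Shapes are built from
primitives — soma disks or perturbed ellipses plus dilated two-segment
polyline strokes for processes — with class-specific parameter ranges:

- ramified: soma Ø 5–8 µm, 4–8 processes ≤ 1 µm wide, 10–25 µm long;
  accepted when area ∈ [60, 240] µm² and circularity ≤ 0.16;
- hypertrophic: soma Ø 12–18 µm, 3–6 processes 2–3 µm wide; accepted when
  area > 250 µm²;
- ameboid: area ∈ [60, 240] µm² and circularity > 0.16, split into a
  nearly-round subpopulation (circularity > 0.5; perturbed disks) and a
  lobed elongated one (0.16–0.5; aspect 0.12–0.28 ellipses with harmonic
  boundary wobble and short stubs). The high-circularity fraction
  defaults to 0.5.

Shapes are validated against the package's own morphometry at
construction and resampled on a miss, so ground-truth labels agree with
the gates by design; the gates, not the shapes, are the scientific
content. Footprints are placed by rejection sampling with a ≥ 5 px
inter-cell clearance (so PSF blur cannot bridge neighbours above
threshold) and a 3 µm border margin; a shape that cannot be placed is
resampled a few times before the scene errors out.

Painting: Iba1 uniform over the footprint (600 gray levels, identical
across classes — no class difference in Iba1 staining intensity is
assumed); Tmem119 with class-dependent soma/process means encoding the
contrast the analysis should detect — ramified 150/400, hypertrophic
130/320 (processes brighter than somata), ameboid 60 ≈ background. These
levels sit in the low half of the 12-bit range like TSA-amplified
immunofluorescence, with marker means for intact cells a few hundred
gray levels and activated cells near background. Cells are extruded over
3–6 contiguous z-slices, blurred with a Gaussian PSF (σ 0.3 µm), then a
planar background (level 40, gradient ± 10, random orientation) and
Poisson–Gaussian noise (shot noise at 1 photon/gray level, read noise
σ 10) are added and values clipped to [0, 4096]. True per-cell means are
recorded from the painted values before blur/background/noise.

What the generator does **not** emulate: real 3D arborization (footprints
are extruded 2D masks, matching a projection-based analysis), touching or
overlapping cells, photobleaching, depth-dependent attenuation, and
structured tissue autofluorescence. Passing recovery tests therefore
demonstrates correctness of the measurement chain under the stated
model, not robustness to densely packed or poorly separable tissue.

## qPCR arithmetic

Technical replicates are averaged per (sample, gene) first. Reference
genes are combined by the arithmetic mean of their CTs; ΔCT uses the
reference-minus-GOI sign convention, so higher expression gives higher
ΔCT and ΔΔCT > 0 means up-regulation. The control-group ΔCT is pooled by
mean (median available) before differencing; fold change is `E^ΔΔCT`
with E ∈ (1, 2] supported (measured primer efficiencies are typically
1.95–1.99). Group-level fold `E^(agg(ΔCT_t) − agg(ΔCT_c))` inverts
exactly under label swap.

## Sample size

`n = 2σ²f/Δ²` with `f(α, β) = (z_{1−α/2} + z_{1−β})²` from normal
quantiles; `f(0.05, 0.2) ≈ 7.85`, so σ = 18.42 and Δ = 42 give n ≈ 3.02.
Published tables sometimes use slightly different f factors (values near
7.6 reproduce printed estimates around 2.9), so `f` is exposed as an
override rather than guessed.

## Evaluation and numerical choices

Pipeline output is scored against truth by greedy one-to-one matching on
decreasing Jaccard overlap with a 0.3 floor (0.6 where a strict match
quality is asserted), standard in segmentation benchmarking. The
confusion matrix rows are truth classes and always sum to truth counts;
unmatched truth cells count as missed, unmatched segmented cells as
spurious. Intensity recovery is the relative error of the total marker
mean on matched pairs — note it conflates segmentation-mask differences
with background-subtraction effects and is reported descriptively.

Problem sizes in the tests and the acceptance script (300 cells over
seven fields for stochastic recovery, 60 cells for match-rate assertions,
exhaustive connected-mask enumeration to 8 px plus seeded samples at
9–12 px) were chosen as the smallest populations at which the asserted
fractions are stable across seeds. Determinism is bit-exact: one
`numpy` Generator seeded from the scene spec drives shape synthesis,
placement and noise, and rerunning a fixed spec reproduces stacks, truth
and output CSVs byte for byte. Floats in CSVs are written with 6
significant digits; coordinates are 0-based (y, x) with y increasing
downward.

## Known limitations

- The constant-threshold contract fails under strong illumination
  differences between images; the threshold helper only standardizes how
  a constant is chosen, it does not make the method adaptive.
- The 20 px marker-channel rolling ball partially flattens wide somata
  (see above); marker means are therefore comparable within a fixed
  configuration, not absolute immunoreactivity units.
- Touching cells are not split; in dense tissue the segmentation merges
  them and morphometry reflects the merged object.
- Circularity near the 0.16 gate depends on the perimeter estimator at
  the few-percent level; cross-configuration comparisons must hold the
  estimator fixed.
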