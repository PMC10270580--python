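# Methods

This note records the models implemented in `colorboard`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
experiments do and do not establish.

## The reference board

The board is a planar card (default 100 × 70 mm, rasterized at 5 px/mm →
500 × 350 px) carrying:

- **Four corner fiducial markers** (default 10 mm), one per corner, ids 0–3
  clockwise from the bottom left. Markers are 4×4-bit square binary patterns
  with a one-cell black border, drawn from a 50-symbol dictionary
  (`board4x4_50`) generated deterministically at import time: candidate
  16-bit codes are visited in a seeded random permutation and accepted
  greedily when all four of their 90° rotations keep Hamming distance ≥ 4
  from every rotation of every accepted code (rotationally symmetric codes
  are excluded). Unique ids per corner plus rotation-unique payloads let a
  single view establish the full board orientation.
- **Reference color stripes** along the sides. Each stripe varies one HSV
  component regularly over [0, 1] (swatch k of n has value k/(n−1), default
  n = 24) with the other two fixed. Pattern A — the default — carries hue
  stripes (S = V = 1) at top and bottom, a saturation stripe (H = 0, V = 1)
  on the left and a value stripe (H = 0, S = 1) on the right, covering the
  HSV cone with one-dimensional families. Patterns B/C/D are reduced
  variants used to study the contribution of each family (D carries no
  hue-varying stripe). HSV→RGB uses the standard hexcone mapping with
  round-half-up 8-bit quantization.
- **A central sample region** that hosts the object being measured.

Board dimensions, stripe widths, swatch counts and resolution are not
physical constants of the method; the defaults above are a size that prints
comfortably on a badge-sized card and leaves a ~72 × 48 mm sample region.
With this geometry, stripe centerlines sampled at 10-px intervals yield 118
(observed, reference) pairs. Larger boards yield proportionally more pairs;
results are insensitive to this count once it comfortably exceeds the number
of unknowns (6 per channel for the order-1 model).

**Digitization.** Printed colors differ from source-file colors in
printer-specific ways that are not worth modeling. The package therefore
treats a rectified scan of the printed board as the color authority:
`digitize_board` re-assigns every stripe pixel from the scan (optionally
through a k×k median filter against scanner noise). Corrections then map
captured colors to *printed* colors, which is the physically meaningful
target.

## Geometry

The pinhole model is `s·[p; 1] = K R (P_w − C)` with the world origin at the
board's bottom-left corner, x right, y up, z out of the board; all board
points have z = 0. Image rasters use the usual top-left origin with y down;
the y-flip lives in the spec's world↔raster maps, with pixel (row, col)
centred on world ((col+0.5)/ppm, H_mm − (row+0.5)/ppm).

- **Detection**: threshold at the mid-range intensity, extract dark connected
  components, keep convex quadrilaterals, decode the cell grid against the
  dictionary under all four rotations. Corner positions are refined to
  subpixel precision by fitting total-least-squares lines to the
  threshold-level contour of the *grayscale* image along each quad edge and
  intersecting adjacent lines. Fitting to the binarized staircase instead
  leaves a ~1 px bias under perspective; the grayscale contour removes it
  (≤0.2 px in rendered tests).
- **Tracking**: sparse pyramidal Lucas–Kanade (3 levels, 21-px windows),
  only attempted when a complete 16-point set is available — anything less
  falls back to detection, which bounds drift accumulation. Failure (point
  out of bounds, textureless window, frame-size change) raises and the
  caller re-detects.
- **Pose**: for ≥ 4 points the plane-to-image homography is decomposed
  (columns of K⁻¹H orthonormalized via SVD, sign fixed so the board lies in
  front of the camera) and polished by Levenberg–Marquardt on reprojection
  error over all points. With exactly 3 points the solution is ambiguous;
  the solver runs a multi-start refinement (structured starts above the
  board) and returns the candidate with the lowest reprojection error. Fewer
  than 3 points is an error. Round-trip accuracy on synthetic projections is
  ~1e-12 mm; lens distortion is assumed removed upstream.
- **Guidance**: the optimal height is `focal / min(W_img/W_board,
  H_img/H_board)` (the board fills the tighter image dimension). The
  guidance arrow runs from the projected board centre to the image centre —
  the projected-board-centre convention is this package's formalization of
  the on-screen arrow, which the source system only shows visually. A
  capture is accepted when |arrow| ≤ 20 px and the height is 1.0–1.5× the
  optimal height.
- **Rectification**: homography from all detected corners, resampled onto
  the board raster with bicubic interpolation and clamping. Bicubic was
  chosen over bilinear because the warp round-trip on stripe pixels
  reconstructs swatch edges measurably better (mean |Δ| 1.8 vs 2.2 levels
  under a moderate perspective warp); the board's piecewise-constant content
  rewards the sharper kernel.

## Color correction

Per channel c ∈ {R, G, B}: `I_ref(x,y) = α(x,y)·I_img(x,y) + β(x,y) + e`.
The coefficient surfaces are polynomials in pixel position: constants
(order 0, the simple linear model), planes `ax + by + c` (order 1, the
default), or quadrics `ax² + bxy + cy² + lx + my + n` (order 2). α and β are
fitted *jointly* per channel by a single OLS solve — for order 1 the design
row is `[x·I, y·I, I, x, y, 1]` — which is the natural least-squares
formulation when both surfaces are unknown. Coordinates are normalized to
[0, 1]² for conditioning; coefficients are stored in the normalized frame.

The first-order default reflects the physical setting: over a badge-sized
board, illumination varies approximately linearly, and the 6-parameter model
resists overfitting the ~118 sample pairs. Minimum pair counts are
unknowns + 2 (2/8/14 for orders 0/1/2). A channel whose design matrix is
rank deficient (e.g. constant observed values make the spatial-gain columns
collinear) falls back to order 0 and is flagged. Corrected values are
clamped to [0, 255] and re-quantized; out-of-gamut results have no defined
meaning in an 8-bit pipeline.

Baselines: `fit_color_checker_baseline` fits the order-0 model on exactly 24
pairs evenly subsampled from the stripes, emulating a discrete 24-patch
color checker; `histogram_match` is the non-parametric per-channel baseline.

## Evaluation and pH reading

`mRMSE` is the mean over R, G, B of the per-channel RMSE between corrected
and reference images over an explicit pixel mask, in 8-bit levels; it is
zero iff the images agree on the mask. `variance_report` measures color
consistency across capture conditions as the population variance of the
object's mask-mean color.

pH reading converts the measured strip color (mean RGB over a centered patch
covering the central 50% of the sample region, or a user mask) to CIE 1931
xy chromaticity via sRGB decoding with the D65 white point and 2° observer.
Black has no chromaticity and maps to the white point by convention. The two
chart points nearest in chromaticity distance define the reading through
inverse distance weighting, `pH = (pH₁·d₂ + pH₂·d₁)/(d₁+d₂)`, with d₁ the
distance to the lower-pH point; an exact color match returns that reference
pH. "Two closest" is interpreted as the two smallest distances; when those
are non-adjacent on the chart (possible when the chromaticity curve folds),
the reading falls back to the adjacent neighbour of the single nearest
point, so interpolation always happens along the curve. With two nodes the
IDW value is convex: readings always lie between the two selected reference
pH values, which also means the method extrapolates *resolution* (values
between chart steps) but never beyond the chart's range.

## The synthetic study

The generator emulates the study conditions end to end:

- **Object of interest**: a seeded 44 × 24 mosaic of uniform-random RGB
  cells tiled row-major into the sample region (equal integer tile sizes,
  remainder pixels keep the background), covering the color space densely.
- **Illumination**: `out_c = E·g_c(T)·(1 + m·(d·p − 0.5))·in_c + ε`, with
  per-channel blackbody gains g(T) (Planck spectrum → CIE 1931 XYZ via the
  multi-lobe Gaussian analytic fit of the 2° color-matching functions →
  linear sRGB, ratioed against 6500 K and normalized to unit mean, so 6500 K
  is neutral and 2800 K boosts red over blue), a linear gain ramp of
  fractional span m along unit direction d over the normalized pixel grid,
  optional global exposure E, and i.i.d. Gaussian sensor noise ε, clamped to
  [0, 255]. The study grid crosses T ∈ {2800, 4000, 6500} K with three ramp
  directions at m = 0.2, noise sd 2. This model was chosen because it spans
  the named conditions (color temperature × lighting direction × noise)
  while containing the order-1 affine family exactly, so ground truth for
  the correction is known. Note that at warm temperatures with E = 1 bright
  stripe pixels saturate; saturation is irreversible and is the main error
  source under those conditions. The oracle tests that require exact
  invertibility set E < 1 so every effective gain stays below 1.
- **Oblique views**: the planar board is warped by the homography of a
  camera at elevation θ (90° = overhead) and 1.2× the optimal height,
  shaded by the Lambertian factor sin θ relative to the overhead view.
  Renders are mipmap-prefiltered (Jacobian-scaled Gaussian) and 3×
  supersampled with box averaging, emulating the area integration of sensor
  pixels; point-sampled warping leaves grid-phase aliasing that masquerades
  as angle dependence. The renderer returns the true projected marker
  corners alongside the image; the viewing-angle sweep rectifies from those
  to isolate resampling and shading effects from detector robustness, which
  is tested separately (all four markers detect reliably down to ~50°
  elevation with this geometry).

**What passing the synthetic study shows — and what it does not.** The
simulation establishes that the geometry, sampling, fitting and reading
stages are correct and that the order-1 SVCM recovers exactly the family of
distortions it models, degrading gracefully with sensor noise and saturation.
Real captures add phenomena the generator deliberately omits: non-linear
tone curves, demosaicing, specular reflections and shadows, non-planar
boards, and printer gamut compression (handled operationally by
digitization, not modeled). Mean corrected stripe error under the nine study
conditions (~8.4 levels, dominated by warm-light saturation) therefore
characterizes this synthetic setting, not any physical camera.

## Numerical choices and degenerate inputs

- OLS via `numpy.linalg.lstsq`; rank checked explicitly for the fallback.
- Pose refinement: `scipy.optimize.least_squares` (LM, tolerances 1e-15).
- Homographies estimated/applied with scikit-image's normalized DLT.
- All generators take explicit seeds; identical inputs give byte-identical
  outputs (there is no hidden global RNG state).
- Empty masks, dimension mismatches, out-of-range angles/temperatures,
  duplicate chart pH values, insufficient or collinear correspondences all
  raise typed errors rather than producing silent results.
- Problem sizes throughout (500 × 350 board raster, 9 conditions, 12-angle
  sweep, 100-pose round trip) are the package's default study scale; they
  run in seconds on one CPU.

## Known limitations

- The fiducial dictionary shares the structure of the widely used 4×4 ArUco
  families but not their exact bit assignments; boards printed from this
  package must be detected by this package.
- The detector assumes reasonably uniform illumination when thresholding
  (mid-range global threshold); deep shadows across a marker defeat it.
- No shadow or specular handling; pH charts with strongly folded
  chromaticity curves can make nearest-two selection ambiguous (mitigated by
  the adjacency fallback).
- Tracking assumes small inter-frame motion (a few px per frame at the
  default pyramid depth) and does not re-validate marker identity between
  detections.
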