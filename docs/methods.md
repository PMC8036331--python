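# Methods

## Scope and model

The package estimates vineyard canopy structure — height H (m), width W (m),
leaf wall area LWA = 2·H·10⁴/s (m² ha⁻¹) and tree row volume
TRV = H·W·10⁴/s (m³ ha⁻¹), with s the row spacing — from multispectral
imagery at two resolutions: a fine grid (default 6.48 cm, the ground-sample
distance of a 95 m flight with a 5.5 mm lens and 3.75 µm detector pitch,
GSD = altitude · pitch / focal length) and a coarse 3 m satellite-class grid.
The two-sided LWA and hedgerow TRV forms are the standard dose-expression
conventions for vertically trained vines; both are homogeneous of degree one
in H, and TRV ≡ LWA · W / 2.

The estimation chain is: NDVI → canopy mask → masked NDVI → IDW interpolation
→ quintile three-class vigour map (fine grid), or raw NDVI → quintile map
(coarse grid, where rows cannot be segmented); per-vine features inside
rectangular sampling polygons; Spearman screening; Ln–Ln OLS with a
residual-normality gate, fitted on single points (SPD) or on vigour-class
means (AD).

## Synthetic scene generator

Because real flight campaigns are not shipped with the package, a generator
produces fully ground-truthed scenes with the statistical structure the
analysis assumes. What it emulates, and how:

* **Layout.** Rows are parallel lines one row spacing apart, oriented by a row
  azimuth (degrees clockwise from north); vines sit every vine spacing along
  each row. The grid is centred in the plot's rotated bounding box; k rows fit
  iff (k−1)·spacing fits in the span, which leaves a strictly positive margin,
  and centres outside the boundary polygon are dropped. Default geometry is
  2.2 m × 1.2 m, typical of double-cordon plantings.
* **Latent vigour.** Per-vine vigour ∈ [0, 1] is a linear spatial trend plus
  2–4 Gaussian bumps plus iid Gaussian noise, clamped. Defaults (trend
  0.006 m⁻¹ across rows, 3 bumps of amplitude ±0.25 at 8 m length scale,
  noise sd 0.05 around base 0.5) give plots with contiguous low/medium/high
  zones over tens of metres. The same seed reproduces the same field across
  growth stages, so repeated calls model one plot observed on several dates.
* **Canopy dimensions.** Height and width are affine in vigour (defaults
  0.50–0.85 m and 0.20–0.40 m at the first stage) and scaled by growth stage:
  1.0 at BBCH 59, 1.5 at BBCH 75 and BBCH 81. The plateau encodes the
  observation that hedging and topping after fruit set freeze the canopy
  envelope; growth from flowering to pea-size berries multiplies dimensions by
  about 1.5.
* **Spectra.** Each vine paints a rectangle (along-row length
  min(vine spacing, 1.2 m), across-row width = true width) whose reflectance
  is affine in vigour per band; defaults give noiseless canopy NDVI 0.70–0.89.
  Background soil (NDVI ≈ 0.2), optional weed patches (circles of
  intermediate NDVI ≈ 0.45, Poisson-placed at 20 patches ha⁻¹) and shadow
  strips immediately north of each row (multiplicative darkening ×0.4)
  complete the scene, followed by iid reflectance noise (sd 0.01) truncated to
  [0, 1]. Truncation rather than resampling: at this noise level the induced
  bias is negligible. A constructor check enforces the separability
  precondition (noiseless canopy NDVI strictly above soil NDVI) that
  threshold segmentation relies on.
* **Satellite degradation.** Coarse pixels are area-weighted block means of
  fine reflectance per band (partial blocks at the raster edge are normalised
  over the area they cover, never truncated); NDVI is computed *after*
  aggregation. This reproduces the two observable consequences of pixel
  mixing: a compressed NDVI dynamic range at 3 m, and attenuated NDVI for
  vines near the plot border whose pixels mix in the surrounding bare ground.
  The bare-soil apron around the plot is 5 m wide by default — deliberately
  not a multiple of the 3 m satellite pixel, since a grid exactly registered
  to the plot boundary is a degenerate configuration that real imagery never
  exhibits and that would suppress edge contamination entirely.

What the generator does **not** emulate: radiometric calibration error,
sun-angle/BRDF effects, orthomosaicking artefacts, terrain slope, georeference
error, canopy gaps or porosity, and spectrally realistic shadows (the
multiplicative shadow model leaves NDVI unchanged in shadow). Passing tests
therefore demonstrate that the analysis chain is correct and that the
platform/aggregation/edge findings follow from resolution and mixing alone —
not that the regressions would attain the same R² on real flights.

## Vigour mapping choices

* NDVI cells with NIR + R = 0 are *missing* (NaN); masked-out background
  cells are *zero* — two distinct states. Only finite cells enter percentiles.
* Automatic canopy thresholding uses Otsu's bimodal split; a manual scalar
  override reproduces operator-chosen thresholds.
* IDW: weights d⁻ᵖ over the k nearest canopy-pixel anchors, defaults p = 2,
  k = 12, output grid = input grid. A cell coincident with an anchor returns
  the anchor value exactly (the interpolant is exact at the data).
* Quintile rule: thresholds are the empirical 20/40/60/80th percentiles
  (linear interpolation) of the in-plot cells of one plot at one date —
  no cross-plot pooling. Low is strictly below P20, high strictly above P80;
  values exactly at a threshold are medium, making medium the closed band.
  A constant surface degenerates to all-medium with a logged warning.

## Sampling and extraction choices

* SUR sampling: random starts uniform on {1..period} at each of the two
  stages (rows, vines within rows). A period exceeding the population selects
  the start unit only, with a warning.
* The sampling polygon is 1.2 m along-row × one full row spacing across-row,
  centred on the vine. Projected area is the pixel-counted area of the
  canopy-mask cells inside the polygon (the polygonised canopy contour), not
  the drawn rectangle.
* Cell membership is centre-in-polygon on the fine grid and exact
  rectangle-intersection area weighting on the coarse grid — a
  resolution-appropriate trade-off (at 6.5 cm the centre rule errs by at most
  a half-pixel ring; at 3 m partial overlap dominates and must be exact).
* Vigour-class assignment per vine is the majority class of its canopy cells;
  ties resolve to medium. On the coarse grid the class of the largest-overlap
  pixel is used.
* A vine is an edge point iff its polygon centroid lies within 3 m of the
  plot border ring — the vine is treated as a point-like sampling unit.
* Field-marked vine identification from imagery is replaced by known synthetic
  coordinates; a GeoJSON import path covers real-world polygons.

## Statistics choices

* Spearman rho is pairwise-complete with averaged ranks for ties; a constant
  variable yields an undefined (NaN) entry with a warning.
* Both regression axes are Ln-transformed; non-positive values are an error
  that lists the offending records rather than silently dropping them.
* The normality gate is a one-sample Kolmogorov–Smirnov test of the OLS
  residuals against a normal with mean and sd estimated from those residuals.
  With estimated parameters this is the Lilliefors setting and the nominal
  p-values are conservative at small n; the accept/reject rule (reject when
  p ≤ 0.05) is applied as-is. Numerically zero-variance residuals (a perfect
  fit) pass the gate with p := 1 and R² = 1.
* SPD and AD fits pool plots, years and stages into one model per response;
  AD averages within (plot, year, stage, vigour class) cells first, dropping
  empty cells with a warning. Satellite analyses reject edge points by
  default. No multiple-testing correction is applied; all four responses'
  p-values are reported.
* Each outcome retains the pieces needed to draw a 95% confidence band for
  the mean response (n, x̄, Σ(x−x̄)², residual MSE) without refitting.

## Numerical and interface conventions

* Projected metric CRS throughout, identified by an opaque label; a
  raster/vector CRS mismatch is an explicit error, never a silent
  reprojection. North-up grids, 0-based indexing, pixel (0, 0) at the
  top-left; the transform stores the top-left corner and square pixel size.
* Rasters are float32 GeoTIFF with ModelPixelScale/ModelTiepoint tags and a
  JSON description carrying band names, transform and CRS label (round-trip
  within 1e-6); vectors are GeoJSON; tables are CSV with full precision
  internally and rounding only at the CSV boundary (LWA/TRV to 2 d.p., NDVI
  to 4 d.p.).
* Every random operation reads a named seed from the run config; artefacts
  carry JSON sidecars with the config hash and seeds, and a rerun with the
  same config is byte-identical.

## Problem sizes

The default desk-scale configuration is one 22 m × 12 m plot (100 vines,
25 SUR-sampled, three stages, 75 database records), which keeps a full
`run-all` under half a minute on one CPU. The reproduction script uses a
40 m × 30 m plot (450 vines, 243 records) — large enough that edge vines are
a minority, as in commercial parcels, while the fine-grid rasters
(~770 × 620 pixels) stay cheap. Both sizes are package choices; all
quantities scale to larger plots through the same configuration object.

## Known limitations

* The latent vigour field and the affine reflectance model are convenient
  abstractions, not calibrated radiative transfer; absolute NDVI levels are
  plausible but not instrument-specific.
* The KS gate with estimated parameters is anti-conservative as a test of
  normality (Lilliefors caveat); it is used here as a reproducible decision
  rule, not as a calibrated hypothesis test.
* AD fits on a single plot rest on very few aggregated points (3 classes ×
  stages); their R² values are correspondingly optimistic and their KS gate
  has little power. This mirrors the method's behaviour on real data.
* Quintile thresholds are per plot per date, so vigour classes are relative
  labels; cross-date class comparisons are not meaningful without an absolute
  NDVI reference.
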