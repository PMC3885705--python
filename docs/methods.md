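# Methods

This note documents the measurement model implemented by `ctcmorph`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not establish about real gallery images.

## Input model

A gallery tile is a square 8-bit image (one grayscale plane or three RGB
planes) containing at most one candidate cell. Channel roles (brightfield,
DAPI, cytokeratin, CD45) are assigned per tile by a CSV manifest rather
than inferred from filenames or plane order, because export layouts vary
by platform and site. RGB composites are treated as three independent
8-bit planes; no color-space conversion is applied. Tiles outside the
typical 80–200 px export range load with a warning, not an error — the
range describes the platform's export, not an algorithmic requirement.

## Thresholding

`cluster_threshold` is exact two-class histogram clustering on the 256
integer levels: it picks the cut `t ∈ [0, 254]` minimizing the
pixel-weighted within-class intensity variance of `{≤ t}` vs `{> t}`
(equivalently maximizing the between-class variance), ties going to the
lowest cut. The implementation is a vectorized cumulative-moment scan and
is tested for exact agreement with a naive 255-point search on every image.

Plain two-class clustering has a known failure mode: when the bright
object covers less than roughly 0.25% of the tile (a small nucleus on a
large tile), splitting the *background noise* yields a larger between-class
variance than isolating the object. The pipeline therefore uses a
stabilized selection by default (`segmentation.threshold_stabilize`):

1. the cut is chosen on a copy smoothed with a 3×3 boxcar (noise sd drops
   ~3×, so the object split wins for objects down to ~0.03% of the tile);
2. the cut is refined to the intermeans fixed point of the **raw**
   histogram (`t = (μ_below + μ_above)/2`, iterated), centering it in the
   intensity gap;
3. the mask is taken from the raw intensities, so with well-separated
   foreground/background levels the mask equals the analytic rasterization
   exactly.

A constant channel has no two clusters; it is flagged `empty`, never
raised, so a gallery run always completes.

## Particle filters and areas

Per channel, in order: connected-component labeling (8-connectivity, so
diagonal boundaries of rasterized ellipses do not split); **border
rejection** (any particle owning a pixel in the first/last row or column is
deleted — the cell is incompletely imaged); **debris filter** (particles
whose mask vanishes under two iterations of binary erosion with a full 3×3
element are deleted; survivors keep their *original* pixels for area
counting, since erosion must not bite into the measured area — the
alternative is exposed as `measure_eroded`); **multi-particle detection**
(≥ 2 survivors, or watershed splitting of a single survivor).

Watershed seeds are the h-maxima of the particle's Euclidean distance
transform with depth `h_depth` = 1 px: the discrete EDT of a smooth convex
particle carries shallow spurious maxima along its medial ridge (depth well
below 1 px), while genuinely touching cells are separated by a neck whose
EDT saddle sits several pixels below the body maxima. Seeds closer than
`h_min` = 4 px merge; a tile is multi-particle when ≥ 2 catchment basins
each hold `A_min` = 30 px (≈ the area of a 2.3 µm disk at 0.37 µm/px —
small enough to catch touching small cells, large enough to ignore
boundary roughness).

Cell area `A_cell` is the total original pixel count of surviving
cytokeratin particles; nuclear area `A_N` likewise for DAPI. Tiles with
`A_N > 0.95 · A_cell` (strict inequality) are rejected as having an
improbable nuclear size — the geometry of fragments in which cytokeratin
only partly covers, or is detached from, a nucleus.

QC rules are evaluated in a fixed, documented order so the primary
rejection reason is deterministic: `empty` → `border_touch` →
`multi_particle` → `nuclear_gt_95pct` → `no_contour`/`fit_failed`. Tiles
whose foreground consists only of debris are reported as `empty` (nothing
measurable remains).

## Shape: contour, ellipse, elongation factor

The shape pipeline contrast-stretches the cytokeratin channel (linear map
of the 1st–99th intensity percentiles onto [0, 255]), auto-thresholds with
the same stabilized operator, and optionally smooths the mask with three
3×3 erosions followed by one dilation. Every particle boundary is traced
with clockwise Moore-neighbor tracing (a deterministic automaton over
(pixel, scan-direction) states, started at each particle's top-left-most
pixel); the longest contour is kept and fitted with the direct
least-squares conic fit constrained to an ellipse (Halir–Flusser, via
`skimage.measure.EllipseModel`). The elongation factor is the ratio of the
fitted major to minor full axis lengths; a moment-equivalent-ellipse
fallback is available (`ellipse.fit_method: moments`).

Two numerical choices matter at this image scale:

- **Boundary offset.** Traced contour points are boundary *pixel centers*,
  which sit on average half a pixel inside the continuous outline; fitting
  them underestimates each semi-axis by ~0.5 px (a 6% error on a 10 px
  semi-minor axis). The pipeline adds the 0.5 px back onto both fitted
  semi-axes (`boundary_offset`); fits to points lying on the curve itself
  use no offset and recover the generating ellipse to 10⁻⁶ relative error.
- **EF on the un-smoothed mask.** The 3-erosion/1-dilation smoothing
  offsets the boundary inward by ~2 px on each side. At ~0.37 µm/px an
  8 µm cell has semi-axes near 10 px, so smoothing inflates EF by 5–7% —
  enough to dominate the shape signal between the study groups (median EF
  1.27 vs 1.17). EF is therefore measured on the raw thresholded mask by
  default; `ellipse.smooth_mask: true` restores edge smoothing for noisy
  or textured material, at the cost of that bias.

## Calibration and derived metrics

The µm/px factor is the ratio of the mean reference diameter of a cell
population (measured in suspension on an imaging cell analyzer) to the mean
equivalent-circle pixel diameter of the same population in gallery images:
`k = mean(d_ref) / mean(2·√(A/π))`. This is the only dimensionally
consistent reading of calibrating image areas against instrument diameters;
one factor is used per acquisition batch. Derived metrics:
`d = k · 2·√(A/π)` (cell and nucleus), `N/C = A_N / (A_cell − A_N)`
(scale-invariant; legitimately above 1 when the nucleus covers more than
half the cell), and EF as above.

## Cohort statistics

Per-sample summaries report median, lower/upper quartile, mean and sd of
each metric over *accepted* cells, with quartiles by linear interpolation
between order statistics (the numpy/R type-7 default, stated here because
quartile conventions differ). Group comparisons are two-sided Welch *t*
(diameter-like metrics) and Mann-Whitney rank-sum (the skewed EF and N/C);
both are always computed and reported. The cohort-level "average median" of
a metric is the unweighted mean of per-sample medians. Storage shrinkage is
`100 · (mean_t48 − mean_t0)/mean_t0` per diameter type (negative =
shrinkage). The rejection report stores exact counts and the exact
fraction; percentages are rounded (one decimal) only at display time.

## Synthetic galleries and ground truth

The generator emulates the platform's per-cell export: one bright cell
body in the cytokeratin channel, a nucleus in the DAPI channel, uniform
background, additive Gaussian noise (default sd 10 on a 150-level
foreground/background separation; optional Gaussian blur, off by default —
no optical PSF model is claimed). A pixel is foreground iff its center
satisfies the analytic ellipse inequality, and the recorded truth areas
are the same lattice counts — ground truth is an exact integer, free of
anti-aliasing ambiguity.

Population defaults are the study groups' summary parameters, as presets
(not fitted models): `ctc_like` d ~ N(7.97, 1.81²) µm, median EF 1.27,
median N/C 1.43; `cultured_like` d ~ N(13.38, 2.54²) µm, EF 1.17, N/C
1.12; diameters truncated at 4 µm; EF drawn as 1 + lognormal (median-
anchored, σ = 0.4, capped at 2.8); N/C lognormal truncated to [0.4, 3.0]
(intact malignant cells: nucleus at least ~30% of the cell area). The
elongation parameterization preserves the equivalent-circle diameter
(a = d√EF/2, b = d/(2√EF)), so size and shape vary independently. Imaging
scale defaults to 0.37 µm/px, the scale implied by the study's size
calibration.

Geometry choices: nuclei are concentric and co-oriented with the cell,
rounder than the cell body (nuclear elongation ≈ √(cell EF)), strictly
contained, with a physical floor of 3.2 px semi-minor (≈ 2.4 µm minor
diameter) — thinner nuclei would be erased by the debris filter and do not
occur in intact cells; tile side is drawn from 80–200 px but capped at
about 8 cell diameters, since gallery exports crop around the detected
event. Failure cases: border tiles place the cell across a frame edge
(verified on the rasterization); doublets are two disjoint cells ≥ 6 px
apart, fully interior; fragments shrink the cytokeratin ellipse to about
half the nuclear area and displace the nucleus until disjoint (or to a
requested partial overlap) — the apoptotic-fragment morphology in which
cytokeratin no longer covers the nucleus; blanks are pure background
noise. Every gallery is fully determined by its seed, byte-identically on
disk.

What passing the synthetic benchmark shows: threshold optimality, exact
filter semantics, shape recovery to a few percent at realistic cell sizes,
100% detection of the modeled failure cases, and correct cohort-level
statistics. What it does not show: performance on real exports with
auto-exposure drift, uneven illumination, texture inside the cell body,
out-of-focus tiles, overlapping leukocytes, or weak cytokeratin
expression — none of which the generator models.

## Problem sizes

The bundled verification suite uses 200-tile galleries for the end-to-end
recovery and QC checks, 100 cells per group for the cohort emulation, 60
paired cells for the shrinkage experiment and 40 cells for the calibration
run — sizes at which the sampling error of each summary is comfortably
below the tolerances being checked while the full suite runs in seconds.

## Known limitations

- The watershed probe flags touching *pairs* reliably but is not a
  splitter: multi-particle tiles are rejected, not separated into cells.
- Orientation is undefined for near-circular cells (EF → 1); downstream
  analyses use EF only.
- The N/C ratio uses projected areas, not volumes; it is not comparable to
  volumetric N/C estimates.
- Per-image thresholding assumes each tile's auto-exposure is roughly
  bimodal; batch-level thresholding is not implemented.
- CD45 is carried as metadata only; leukocyte identification is out of
  scope.
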