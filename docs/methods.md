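# Methods

`condensia` quantifies mesenchymal condensations — the dense multicellular
aggregates that initiate cartilage and bone formation — in two imaging
settings: conventional brightfield micromass cultures, and fluorescence
time series of cultures confined in rectangular microgrooves. This note
documents the models, estimators, defaults, and limitations.

## Micromass segmentation

Brightfield condensations appear as dark, roughly convex masses on a
bright background. The pipeline is:

1. **Grayscale + polarity.** RGB inputs are converted with standard luma
   weights (0.2126, 0.7152, 0.0722). Intensities are rescaled to [0, 1]
   and, for dark-object inputs (the default), inverted immediately so that
   every later stage sees bright foreground. Normalizing polarity *before*
   contrast enhancement makes the pipeline exactly symmetric under
   intensity inversion: inverting an image and flipping the
   `dark_objects` flag yields a bit-identical label map, which would not
   hold if CLAHE (a non-linear, non-involutive operator) ran first.
2. **CLAHE** (tile 64 px, clip limit 0.01) followed by a Gaussian low-pass
   (σ = 2 px). Both are unreported details of the original protocol and
   are exposed in `SegmentationConfig`.
3. **Global Otsu** binarization. A uniform image raises
   `DegenerateImageError`. Full-frame inputs with no structure beyond
   pixel noise are rejected earlier by a flat-field check (robust 2–98
   percentile range < 8 robust noise SDs, measured before CLAHE — CLAHE
   would stretch pure noise to full range and Otsu would then happily
   split it).
4. **Morphological opening then closing** with 2-px disks (noise specks
   and small holes). The composition closing∘opening is idempotent, so
   re-cleaning a cleaned mask is a no-op — a property the tests assert.
5. **Size floor**: components with strictly fewer than `min_object_px`
   (default 24) pixels are removed; a 24-px component survives.
6. **Border suppression**: a border-touching component whose mean
   intensity does not exceed that of its 3-px surrounding ring (in the
   working frame) is an illumination artifact — in the original polarity
   it is a structure *lighter* than its surroundings — and is removed.
   Genuine condensations touching the border are darker than their
   surroundings and survive.
7. **Watershed with minima imposition.** The Euclidean distance transform
   of the mask is smoothed (Gaussian, `dist_smooth_sigma` = 1.5 px) and
   seeds are taken as the connected regional-maximum plateaus of the
   h-reconstruction (reconstruction by dilation of `dist − h` under
   `dist`, `minima_depth_h` = 2 px). This is the classical
   extended-extrema / minima-imposition construction: basins separated by
   a saddle shallower than `h` produce one seed, including the twin
   equal-height-peak case. Components whose peak is shallower than `h`
   keep a single seed at their distance maximum so no object is lost.
   The smoothing step matters in practice: the distance ridge of an
   elongated object is nearly flat, and a few pixels of boundary
   raggedness otherwise create spurious extrema and systematic
   oversegmentation.

On synthetic scenes with ≥ 5 px gaps, ≥ 200 px² objects and noise
SD ≤ 0.05, the label count matches the generated count in 100/100 seeded
scenes (the suite requires ≥ 95).

## Shape descriptors

Eleven descriptors per region: area, perimeter, eccentricity, minor/major
axis, aspect ratio (major/minor), roundness, number of condensations in
the image, roughness, distance, and occupancy.

- **Moment ellipse.** Axes come from the eigenvalues of the normalized
  second-central-moment matrix with the +1/12 pixel-extent correction
  (each pixel treated as a unit square); eccentricity is the focal
  distance over the major axis length.
- **Roundness** = 4·Area/(π·Major²); 1 for a circle, → 0 when elongated.
- **Perimeters.** The boundary is traced by marching squares at level 0.5
  and simplified with Douglas–Peucker at 0.8 px before measuring length;
  the raw staircase contour overestimates smooth perimeters by ~5%, which
  would bias roughness of convex regions to ≈ 0.95 instead of 1. The
  convex perimeter is the convex hull length of the unsimplified
  vertices. **Roughness** = convex perimeter / perimeter is reported
  unclipped — rasterized convex shapes land within ~1% of 1 on either
  side, and clipping would collapse a convex population to a degenerate
  constant.
- **Occupancy.** The circumscribing circle takes the two most distant
  region pixels as diameter endpoints (farthest pair over convex-hull
  vertices); occupancy is the fraction of that circle's area covered by
  region pixels. ≈ 1 for a disk, ≈ 4/(π·d) for a thin line of length d.
- **Distance** = mean centroid distance to the 4 nearest neighbouring
  regions; with fewer than 4 neighbours the mean runs over those
  available, and a lone region yields NaN with a warning.
- Calibration (µm/px) scales lengths linearly and areas quadratically;
  dimensionless descriptors are unaffected.

Degenerate regions: single pixels have roughness 1 by convention;
occupancy requires ≥ 2 distinct pixels.

## Descriptor ranking by linear discriminant

Two descriptor populations (e.g. facial vs limb-bud condensations) are
pooled, standardized jointly (sample SD, ddof = 1), and a two-class
Fisher discriminant is fitted with the pooled within-class covariance and
equal priors: `w = S_w⁻¹ (µ_a − µ_b)`, with a small ridge
(1e-6 · trace/p) against near-singularity. Descriptors are ranked by
|w|; higher magnitudes contribute more to class separation. A constant
descriptor receives weight 0 and ranks last (with a warning) — it cannot
be standardized but also carries no information. The direction is
cross-checked against scikit-learn's eigen-solver LDA in the tests; the
reported `separation` is the Mahalanobis-style distance between projected
class means in pooled-SD units. Numeric weight values from real data are
not reproducible from published figures; only the ranking semantics is
relied upon.

## Groove profiling

A groove constrains growth along one axis. All quantities derive from
1-D profiles in µm coordinates:

- **Length**: FWHM of a peak in the major-axis profile (mean over the
  groove's short axis).
- **Width**: FWHM of the minor-axis profile computed with the averaging
  restricted to that peak's half-max interval along the groove — the
  condensation's own length extent, not the whole groove.
- **Half-max reference.** Crossings are evaluated at
  `peak height − prominence/2` (via `scipy.signal.peak_widths` with the
  peak's prominence data), which is invariant to constant background
  offsets. Hoechst intensities are not comparable across live-imaging
  frames (dye accumulation), so prominence — not absolute height — is the
  density proxy.
- **Detection floors.** Peaks need topographic prominence ≥ 5× the
  profile's robust noise (1.4826·MAD of first differences / √2) — the
  largest pure-noise excursion in a few-hundred-sample profile reaches
  ~4σ prominence — and FWHM ≥ 10 µm (one nuclear diameter; a
  sub-nuclear peak cannot be a multicellular aggregate).
- **Aspect ratio**: length/width in width-constrained grooves
  (25–200 µm), where values < 1 are possible and meaningful (wide flat
  condensations); longest/shortest (≥ 1) in 300-µm grooves and
  unconstrained plates.
- **Density**: condensations per 100 µm of groove length.
- **Backward tracking.** Every final-frame condensation opens a track
  (tracks ≡ final-frame condensations, always). Going backwards, tracks
  link to the nearest unclaimed peak within
  `max(10 µm, 0.5 × length)`, greedily by distance with exclusion; a
  frame with no match marks the establishment time.
- **Plateau time**: the earliest timepoint after which a per-timepoint
  mean stays within ±10% of its final value. For logistic growth this
  recovers the closed-form band-crossing to within one frame.
- **Marker fraction** (e.g. Sox9⁺): nuclei are local maxima of the
  nuclear channel inside a region above a detection threshold (Otsu of
  in-region intensities by default); the fraction with marker intensity
  above threshold is reported.

Truncation: a condensation whose half-max interval hits the profile end
is flagged `end_clipped`; a measured width never exceeds the groove's
short-axis extent (`width_clipped`).

## Synthetic data

The generator provides exact ground truth for every stage.

- **Micromass scenes**: dark ellipses (or branched unions of overlapping
  ellipses) on a bright background with additive Gaussian noise; default
  background 0.8, objects 0.3, noise SD 0.02–0.05, areas 300–900 px²,
  axis ratios 1–2, ≥ 5 px gaps enforced by Euclidean-disk dilation.
  Rasterized areas land within 5% of the requested area for ≥ 200 px²
  objects. `scene_label_map` re-renders the same seed's objects as a
  perfect instance segmentation for descriptor-level experiments.
- **Groove series**: each condensation is a separable anisotropic 2-D
  Gaussian whose FWHMs follow logistic growth
  `F(t) = F_final σ(r (t − t₀))` (defaults t₀ = 8 h, r = 0.5 h⁻¹, so
  size saturates on the observed scale of ~17 h), with a linear
  amplitude ramp standing in for densification. Frames default to 30-min
  intervals over 36 h (72 frames). Gaussians make the FWHM truth
  analytic; noise is additive Gaussian (Poisson optional).
- Pixel calibration defaults to 1 µm/px and is configurable everywhere;
  the experimental calibration is instrument-specific and not assumed.

What the generator does **not** emulate: brightfield optics (shading,
phase halos), cell-scale texture, nuclei inside condensations, drift,
photobleaching, or condensation merging/splitting over time. Passing the
recovery suites therefore demonstrates estimator correctness under the
stated noise model, not robustness to every property of real microscopy.

Known estimator bias: a Gaussian condensation whose width approaches the
groove width has truncated tails, which raises the prominence base and
shrinks the measured FWHM by a few percent (e.g. ~5% when the FWHM is
half the groove width). This is inherent to prominence-referenced FWHM
on a bounded support and is the regime the `width_clipped` flag reports.

## Problem sizes used in the verification suites

100 seeded scenes (400×400 px, 8 objects) for count recovery; 100 seeded
endpoint grooves (600×100 µm, 2–3 condensations, SNR ≥ 8) for FWHM/count
recovery; 30 seeds for discriminant rank recovery; 8 random convex
polygons against the exact polygon-geometry oracle; 72-frame series for
plateau and tracking checks. The full suite runs in about 90 s on one
CPU.
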