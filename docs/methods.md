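# Methods

This note records the quantitative definitions, default parameters and
numerical choices behind `cytoquant`, and what the synthetic-data generators
do and do not emulate.

## Condensate detection and interaction scoring

A condensate-based protein–protein interaction assay reads out binding as
the co-localization of bright intracellular condensates in two fluorescence
channels. Per image (one cell ROI per image):

- **Detection.** Pixels above a threshold are labelled with 8-connectivity;
  components smaller than 4 px are discarded as shot noise.
- **Threshold policies.** The default `"auto"` estimates background as the
  image median and sets the threshold at median + 3 × 1.4826 × MAD (the MAD
  scaled to a Gaussian σ). Sparse puncta over a dominant, roughly uniform
  background give a *unimodal* histogram, where Otsu's bimodal criterion
  systematically over-thresholds and clips spots to their cores, biasing the
  intensity-fraction statistics below. Otsu (`"otsu"`), fixed values
  (`"fixed:V"` or a number) and percentiles (`"pct:P"`) remain available for
  data that do fit those assumptions.
- **SNR.** Defined as (integrated intensity inside detected condensates) /
  (total ROI intensity), a fraction in [0, 1]. The denominator is the whole
  single-cell ROI, not a background annulus.
- **Colocalization.** Greedy global nearest-centroid matching between the
  two channels' particle sets; pairs farther than `max_dist_px` are not
  matched. A cell is interaction-positive when at least one matched pair
  exists.
- **Efficiency.** 100 × (positive cells) / (co-transfected cells).
- **PI (interaction index).** (efficiency / 100) × mean SNR over positive
  cells; 0 when no cell is positive.

## Interaction matrix

Raw PI values for each bait (GTPase) × prey (effector) pair are placed in a
labelled matrix; unmeasured pairs stay NaN and are distinct from measured
zeros. Scaling divides by the maximum of a scope so the scope maximum is
exactly 1 — per effector column by default (each effector compared across
GTPases), or globally. Gene-family reduction takes the maximum over member
effectors (a family is "hit" if any member is). Both axes are clustered with
complete linkage on Euclidean distances; the flat partition is chosen by
bootstrap cluster stability: columns (for row clustering) are resampled with
replacement, the axis re-clustered, and a cluster counts as reproduced when
some bootstrap cluster reaches Jaccard overlap ≥ 0.5. Singleton clusters are
trivially "reproducible" and are excluded from the score; ties across k go
to the smaller number of clusters. Clustering is performed on the scaled
matrix with NaN imputed as 0 (unmeasured and screen-negative are rendered
identically, as in a heatmap).

## Cell motion

Tracks are centroid positions on a uniform time grid, in math coordinates
(x right, y up, micrometres).

- Directionality = net displacement / total path length; speed = total path
  length / elapsed time.
- Turning angle θ = arccos(a·b / |a||b|), clamped to [−1, 1] before the
  arccos to absorb rounding.
- Windowed kinematics over a 6-step window: Speed(t) = (Σ_{k=−2..3}
  |C_{t+k} − C_{t+k−1}|)/6 and Direction(t) = (C_{t+3} − C_{t−3})/6 (the
  telescoped mean velocity). The window touches C_{t−3} … C_{t+3}, so valid
  frames are 3 ≤ t ≤ T−4 (0-based, T frames).
- Directional autocorrelation at lag L: the mean cosine between unit step
  vectors separated by L, pooled over cells; tracks sampled faster than the
  analysis step are decimated (the analysis step must be an integer multiple
  of the sampling interval); zero-length steps are excluded. For the
  wrapped-normal persistent random walk used in testing, the lag-1 mean
  cosine has the closed form exp(−σ_rad²/2), which anchors the Monte-Carlo
  recovery tests.

## Cell geometry

- **Segmentation.** Median filter (radius 2 px) → threshold at the mean of
  strictly positive filtered intensities → morphological closing (radius
  2 px) → largest 8-connected component → fill holes. The positive-mean
  threshold is appropriate for a bright cell on a dark, mostly-zero
  background; it is *not* a general-purpose threshold.
- **Boundary.** Moore-neighbor tracing from the topmost-leftmost boundary
  pixel with Jacob's stopping criterion, oriented counterclockwise in math
  coordinates. A hand-rolled tracer is used because subpixel iso-contour
  routines do not return the ordered 8-connected pixel chain that windowing
  and per-pixel normals require.
- **Normals.** For each boundary pixel, a quadratic is fitted to a 5-point
  window (half-window 2) in a chord-aligned local frame — the abscissa runs
  along the chord between window endpoints, which removes the
  vertical-tangent degeneracy of a fixed y = f(x) fit. The normal is
  perpendicular to the fitted tangent and oriented inward by probing the
  mask at ±1.5 and ±2.5 px; ambiguous probes (thin protrusions) fall back to
  the centroid direction and are flagged.
- **Membrane region.** Each boundary pixel plus 5 steps inward along its
  normal (rounded to pixels, clipped to the mask). On a disk of radius 40 px
  this covers the outer ~6 px rim with area ≈ perimeter × depth.
- **Wedge and radial bands.** The protrusive wedge is all mask pixels whose
  bearing from the centroid lies within ±45° of the movement direction.
  Each wedge pixel's depth fraction is (R − d)/R, where d is its distance
  from the centroid and R the boundary distance along its ray (720-bin ray
  march, 0.5-px steps): [0, 0.1) = leading edge, [0.1, 0.5) = arc area,
  [0.5, 1] = center. For a disk these occupy 19% / 56% / 25% of the wedge.
  Rays through non-star-shaped boundaries flag the partition.
- **Edge velocity.** The boundary of frame t is split into 60 contiguous
  windows of near-equal pixel count anchored at the topmost boundary pixel.
  Velocity per window is the mean change in signed Euclidean distance
  (inside-positive) between frames, divided by Δt; the difference field is
  Gaussian-smoothed (σ = 1.5 px) before sampling to suppress the ±0.5-px
  quantization of pixelated distance transforms. Outward motion
  (protrusion) is positive.
- **Shape.** Area, perimeter, second-moment-ellipse aspect ratio and
  circularity 4πA/P² from standard region properties; perimeter is measured
  through pixel centers, so small shapes read slightly below their
  geometric perimeter.

## Stress fibers

Median (1 px) + Gaussian (σ = 1 px) filtering, Otsu threshold (fiber images
are high-contrast and quasi-bimodal), 8-connected labelling, then keep
components with 10 ≤ area ≤ 150 px and second-moment aspect ratio > 5.
Orientation is the axial angle in [0°, 180°) from central second moments
(θ = ½·atan2(2µ₁₁, µ₂₀ − µ₀₂) with y up). Because fibers are axial (no head
or tail), the mean orientation uses the double-angle transform, and the
angle deviation is the mean acute axial difference from the reference axis
(the axial mean by default, or a supplied axis such as the cell's polarity
axis).

## Adhesion puncta

Pixels inside the intensity band (default 1200–4500 a.u.) are labelled;
components are kept when their mean intensity is in the band and their size
is inside the size band (default 0.5–15). The size band is interpreted as
area in µm² by default; an equivalent-circle-diameter mode is provided
because published size windows are sometimes quoted either way.

## Kinetics

Recovery (or formation) curves are normalized by the mean of all pre-event
frames (single-frame mode available) and fitted post-event with
F(t) = F0 + (plateau − F0)(1 − e^(−kt)), time origin at the first post-event
frame. F0 is estimated rather than pinned to the first post-bleach sample
(noise robustness). Derived quantities: t½ = ln 2 / k; mobile fraction =
(plateau − F0)/(pre-level − F0); immobile = 1 − mobile. k is bounded to
[1e−12, 1e6] s⁻¹ and results flag fits that land at a bound. A model-free
half-time (linear interpolation of the first half-level crossing) is
provided as a cross-check.

## Synthetic data generators

Generators produce inputs with machine-readable ground truth so every
quantification can be validated by recovery. They emulate the *geometry and
bookkeeping* of the corresponding experiments — spot placement with minimum
separation, truncated-Gaussian SNR draws, anti-aliased bars, wrapped-normal
persistent random walks, drifting masks with optional wedge/rim intensity
painting, plateau-disk puncta, exponential recovery with Gaussian noise.
They do not simulate optics (PSF, shot noise statistics, bleaching),
cell-to-cell morphological variability or segmentation failure modes; tests
built on them validate the estimators, not robustness to real-microscope
artifacts. Ground truth is recounted from the emitted arrays (e.g. realized
in-spot intensity fraction, realized positive count), so recovery tests
compare against what was actually drawn, not merely the requested
parameters.

## Defaults worth knowing

| Parameter | Default | Why |
| --- | --- | --- |
| condensate `min_area_px` | 4 | rejects single-pixel shot noise |
| condensate threshold | `"auto"` (median + 3·1.4826·MAD) | unimodal background; see above |
| colocalization `max_dist_px` | 3 | sub-spot-radius proximity at typical sampling |
| PI scaling scope | per effector column | compares GTPases within each effector readout |
| cluster bootstrap | 100 resamples, Jaccard ≥ 0.5 | standard cluster-stability recipe |
| autocorrelation step | 10 min | typical time-lapse analysis interval |
| membrane depth | 5 px | thin cortical band at ~0.2–0.3 µm/px |
| wedge half-angle | 45° | quarter-plane around the movement direction |
| boundary windows | 60 | ~4–10 px windows on typical cell perimeters |
| edge-velocity smoothing | σ = 1.5 px | removes distance-transform quantization |
| fiber bands | 10–150 px, AR > 5 | excludes specks and merged sheets |
| adhesion bands | 1200–4500 a.u., 0.5–15 µm² | standard puncta gating windows |
| FRAP pre-frames | 30 (CLI) | long baseline for a stable normalization |

## Limitations

- Single-cell ROIs are assumed; no multi-cell scene parsing or tracking
  linkage is included.
- The wedge/radial-band partition assumes an approximately star-shaped cell
  around its centroid; violations are flagged, not corrected.
- The membrane region is a per-pixel construction and can leave isolated
  1-px holes on strongly curved boundaries; its area tracks
  perimeter × depth rather than perimeter × (depth + 1).
- One-phase association only; no reaction–diffusion FRAP models,
  double-exponential fits, or bleach-depth corrections.
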