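# Methods

## Pipeline model and assumptions

`leakyseg` segments adherent cells from a single nuclear stain whose dye
"leaks" into the cytosol: the nucleus is bright (seed), the cytosol is
weak but detectable (body outline), and the background is a smooth uneven
illumination field plus detector noise. The pipeline assumes:

- 2-D analysis of a standard-deviation (SD) Z-projection; no 3-D
  segmentation. The SD projection maps each pixel to the SD of its
  intensities along Z, so signal that varies axially (a cell moving
  through the confocal section) is enhanced while static offsets vanish.
- every cell contains exactly one dominant intensity maximum (its
  nucleus). Overlapping nuclei (3-D growth, heavy clumping) produce
  under-segmentation by design.
- sub-confluent fields: a fully confluent frame raises the global mean,
  hence the capped background image, and can suppress the leaky signal.

## Tunable parameters

All constants live in `SegmentationParams`, in physical units, and are
converted to pixels through the image calibration (default 0.6 µm/px
laterally, 1.51 µm slice spacing — a typical confocal acquisition for this
kind of material, and the calibration the defaults were tuned for):

| parameter | default | unit | role |
|---|---|---|---|
| `cap_multiplier` | 3 | – | intensity cap of the background image, × global mean (zeros included) |
| `sigma_background` | 100 | µm | heavy blur that turns the capped frame into the background image |
| `rolling_ball_radius` | 100 | µm | rolling-ball pre-flattening; larger than a cell so the cytosol is untouched |
| `sigma_smooth` | 1 | µm | light smoothing after the rolling ball |
| `sigma_watershed` | 2 | µm | extra blur before maxima detection / watershed |
| `cytosol_threshold` | 1 | gray | cytosol mask threshold on the flattened frame |
| `noise_multiplier` | 3 | – | maxima prominence, × mean of **non-zero** gray values |
| `min_area` | 200 | µm² | strict lower bound on object area (debris filter) |

Note the deliberate asymmetry: the cap multiplier uses the global mean
*including* zeros, while the watershed noise tolerance uses the mean of
*strictly positive* pixels only.

## Numerical choices

- **SD estimator**: sample SD (n−1 denominator) by default, matching the
  common Z-projector convention; `ddof=0` switches to the population SD.
  Downstream thresholds are ratio-based, so the choice is largely
  inconsequential. A single-slice stack projects to zeros.
- **Clamping**: the double subtraction clamps negatives to zero so the
  gray-value-1 threshold is well defined (integer image pipelines clamp
  implicitly; we do it explicitly in floating point). All processing after
  projection is float64; integer conversion happens only at export.
- **Gaussian boundary mode**: edge replication (`nearest`); configurable
  per call. Constants are preserved exactly and interior impulse mass is
  conserved because the discrete kernel is normalized.
- **Rolling ball**: a true ball structuring element
  (`skimage.restoration.rolling_ball`), not the paraboloid approximation
  some packages use — a possible small numerical difference from such
  implementations. Radii above 24 px are computed on a proportionally
  downscaled copy and the background is upsampled before subtraction (the
  shrink strategy common for large balls); on flat frames this path is
  exact and on slow ramps (≲ 0.05 gray/px, slow relative to the ball's
  curvature) residuals stay below one gray value. Steeper ramps leave a
  discretization residual that grows with slope.
- **Maxima / noise tolerance**: "prominence" is implemented as h-maxima —
  a maximum survives if it rises at least the tolerance above the saddle
  connecting it to a higher maximum. Equal-height plateau maxima are
  merged into a single seed (8-connected labeling of the h-maxima mask),
  preventing spurious splits. A frame with no positive pixels yields a
  fully-foreground particle mask (nothing to split) and a warning.
- **Connectivity**: components are labeled 8-connected; watershed lines
  from the library separate basins only 4-connectedly, so diagonal
  contacts across line corners are explicitly broken (the lower-right
  pixel of each conflicting diagonal pair becomes line). This is the
  weakest correction that guarantees a 1-px line disconnects basins under
  8-connectivity.
- **Size filter**: strictly "bigger than" `min_area`; at 0.6 µm/px the
  200 µm² bound keeps a 556-px object (200.16 µm²) and drops 555 px
  (199.8 µm²). Survivors are relabeled 1..K in raster order of first
  pixel. Edge-touching cells are kept by default; `exclude_edges` drops
  them for comparisons against counts of fully-contained cells.
- **Circularity**: `4π·A/P²`, clamped at 1 (tiny regions can exceed 1
  through perimeter underestimation); a single-pixel region scores 1 by
  convention. The perimeter uses the Crofton 4-direction estimator, whose
  error on rasterized disks is < 2 % from radius ≈ 20 px (0.6 % at 40 px);
  naive edge counting was rejected (≈ 27 % bias on disks). The formula
  includes the factor π so that a perfect circle scores exactly 1.
- **Aspect ratio**: major/minor axis of the ellipse with the region's
  second-order central moments; degenerate collinear regions get a
  minor-axis floor of 1 px.

## Evaluation protocol

The human counting categories are formalized deterministically:

- a detection **contains** a cell when it holds > 50 % of the cell's area;
- **correctly segmented**: > 90 % of the cell's area inside its best-match
  (by IoU, ties to the lower label id) detection, the detection's best
  match is this cell, the detection contains no second cell, and the
  detection is at most 2× the cell's area;
- **missed**: no detection overlaps the cell;
- **under-segmented**: cells sharing a detection that contains ≥ 2 cells
  (the largest-overlap member counts as the one true positive, the rest
  as false negatives), or a single cell whose detection frame exceeds the
  configurable `frame_area_ratio` (default 2×) — a heuristic stand-in for
  the human judgement "frame much larger than the actual cell", not a
  published rule;
- **over-segmented**: everything else that overlaps a detection (partial
  detections and splits); the largest fragment counts as a true positive;
- detections overlapping no cell are **debris** / false positives.

Every ground-truth cell lands in exactly one category, so
`manual = correct + missed + under-members + over` holds by construction
and is asserted on every fixture. Unmatched cells contribute IoU 0 to the
mean rather than being dropped (conservative). Pooling sums counts and
weights per-image IoU by cell count.

## Synthetic data: what it emulates, what it does not

`generate_scene` renders elliptical cells (Gaussian-perturbed radii,
area-preserving random eccentricity up to 1.6, random orientation) with a
bright nuclear core (concentric, slightly offset) and a weak cytosolic
plateau, over a smooth illumination field (tilted plane + broad bump),
with iid Gaussian detector noise per pixel and slice. Defaults: 512×512
16-bit fields at 0.6 µm/px (≈ 307 µm across), 5 slices at 1.51 µm,
17 cells of radius 22 ± 2.5 µm (≈ 1500 µm² projected — a typical spread
mammalian cell), nuclei 8 ± 1 µm, nuclear:cytosolic intensity 12000:600
(a 20:1 "leaky" contrast with detector gain set short of nuclear
saturation), gradient amplitude 800 (comparable to the cytosolic signal,
so background subtraction is genuinely exercised), noise SD 50.

Axially, the cell signal follows a smooth Gaussian profile (the section
moving through the cell) and the background is modulated by iid per-slice
factors N(1, 0.05) emulating laser-power/focus drift. The per-slice
independence matters twice over: it keeps the SD projection informative,
and it keeps the background variation incoherent with the cell profile —
an earlier deterministic (cosine) modulation produced systematic
covariance with the axial profile that suppressed the cytosolic SD near
gradient maxima, an artifact of the model rather than of any microscope.

The benchmark suite (`generate_benchmark`, 8 images × 17 cells = 136
cells, clumping 0.2, per-image seeds spawned from one master seed) mirrors
the size of a realistic manual-evaluation set and is the problem size used
throughout the tests; one suite segments and scores in a few seconds.

Not emulated: optical PSF and depth attenuation, photobleaching, 3-D cell
morphology, overlapping nuclei, confluent layers, debris and staining
artifacts. Consequently the synthetic benchmark probes the pipeline's
mechanics (background removal, seeding, splitting, measurement, scoring),
not its performance on difficult real material — passing it shows the
algorithm is implemented coherently, not that real images of any
particular cell line will score as well.

## Known limitations

- Touching cells are split only where their nuclei produce separate
  maxima; merged nuclei under-segment by design.
- The rolling-ball downscale path trades a sub-gray-value approximation
  error for tractability at 100 µm radii.
- The evaluation's `frame_area_ratio` rule is a heuristic formalization of
  a human judgement and is flagged as such.
- ROI-archive export for ROI-manager tooling is not implemented; outputs
  are label TIFFs, CSV tables, JSON reports and PNG overlays.
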