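# Methods

## Scope and model

`embryostager` re-implements the quantitative analyses behind a two-level
staging system for medfly (*Ceratitis capitata*) embryogenesis derived
from long-term light-sheet recordings of nuclear-labelled embryos: embryo
length as a function of developmental time, blastoderm nuclei area and
density in a posterior analysis window, three-dimensional pole-cell
nucleus counting, germband-tip migration kinematics, and stage-duration
statistics across datasets.  The staging model has two levels: six
embryogenetic events (I blastoderm formation, II early gastrulation,
III germband elongation, IV germband retraction, V dorsal closure,
VI muscular movement) partitioning seventeen stages (I: 1–5, II: 6–7,
III: 8–11, IV: 12, V: 13–15, VI: 16–17).

Axis conventions follow the recording geometry: `x` is the illumination
axis, `y` the sample-rotation axis (anterior–posterior after alignment)
and `z` the detection axis.  2D frames are z-maximum projections with
rows along `y`; stacks are ordered `(z, y, x)`.

Because the original ~60-hour recordings are a large external accession,
the package ships a synthetic-data generator that emulates their
statistical structure with exact ground truth; every pipeline is
validated against that ground truth at desk scale.  What those tests do
and do not show about real data is discussed under *Limitations*.

## Image pipelines

**Embryo length** (per aligned frame): crop → 3×3 box mean smoothing →
local-mean threshold in a 150×150 window (strictly above the windowed
mean, edge-replicated) → largest 8-connected component → convex hull →
largest hull extension along `y`, reported as an inclusive pixel count
(max − min + 1).  Length series are normalized to the first frame and to
the fraction of the recorded span; cross-dataset curves are linearly
interpolated onto 1000 evenly spaced normalized timepoints before the
pointwise mean and sample SD (n−1) are taken.  The grid density is a free
choice (the alignment granularity is not otherwise constrained); 1000
points oversample a ~130-frame recording comfortably.

**2D nuclei** (posterior 150×150 window, placed one window-length
interior to the posterior extreme of the Otsu-segmented embryo and
laterally centred on its centroid column): Gaussian smoothing (sigma 2 px)
→ local-mean threshold (window 15, or 10 for the post-13th-division
timepoint) → morphological hole filling → multi-scale Laplacian-of-
Gaussian seeding (10 log-spaced sigmas; published ranges (5, 15) and
(1, 10)) → seeded immersion watershed on the inverted smoothed image →
multiplication with the threshold mask → removal of border-touching
objects.  Counts, per-object pixel areas and count-per-window-area
densities follow.

**3D pole cells**: crop → rigid rotation about `y` by the per-dataset
angle (−40°, −7°, +41°, +13°; anisotropic stacks are first resampled to
cubic voxels with linear interpolation) → scale-normalized LoG filter
(sigma 3 px by default; the "3×3 range" wording is ambiguous between
sigma and kernel size, so the parameter is exposed) → local-mean
threshold (window unstated in the original description; defaults to the
2D setting of 15) → hole filling → 3D LoG seeding → 3D seeded watershed →
multiplication with the threshold mask → object count.

**Germband tip**: manual annotations (time, row, col) are reduced to a
running sum of straight Euclidean steps (× pixel size) and per-interval
speeds.  Straight segments underestimate the true path along the curved
dorsal surface; this is inherent to discrete manual annotation and is
not corrected.

## Operator semantics

Several deliberately pinned-down details, chosen where the published
wording leaves room:

* "N×N pixel range" is read as the kernel size for the mean filter and as
  the Gaussian sigma for Gaussian smoothing (the conventional parameter);
  both are configurable so either reading can be reproduced.
* Thresholds are strict (`value > mean`), so a perfectly flat region is
  all background.
* Local windows are centred; an even window spans one extra pixel on the
  low-index side (`[i − w//2, i + (w−1)//2]`).  A window covering the
  whole image degenerates to the global mean.
* Otsu's threshold is searched over the distinct intensity values (no
  histogram binning); ties take the smallest threshold; constant images
  are rejected.
* Connectivity is maximal by default (8 in 2D, 26 in 3D) to avoid
  spuriously split nuclei; hole filling uses the complementary minimal
  background connectivity.
* The seeded immersion watershed floods from the seeds in order of
  increasing relief value with ties broken by (relief value, insertion
  order, row-major coordinate) — the classical immersion formulation
  leaves plateau assignment open, and this fixes it reproducibly, down to
  bit-identical label maps.  Seeds outside the mask are dropped with a
  warning; mask regions unreachable from any seed stay unlabelled.
  In the nuclei pipelines the watershed is flooded within the threshold
  mask; combined with the subsequent mask multiplication this leaves the
  published composition unchanged on segmented regions while keeping
  unsegmented background unlabelled.
* Component-size ties in `largest_component` resolve to the component
  whose first pixel comes earliest in row-major order.
* `measure_embryo_length` is exactly invariant to a constant intensity
  offset, and hull extents are reflection-invariant.

Operators accumulate window sums exactly for integer-valued images
(sums of integers are exactly representable in float64), which is what
makes the brute-force oracle comparisons in the test suite bit-exact.
On non-integer data, decisions for pixels within float rounding of the
local mean are platform-dependent in the usual way.

## Synthetic-data generator

The generator is a pure function of its spec and seed (bit-identical
re-runs) and produces:

* **Embryo movies** — an ellipse (semi-axes `a` along y, `b` along x)
  whose `y` semi-axis follows a relative-length trajectory over time,
  filled with uniform cytoplasmic signal over background, with surface
  nuclei rendered as Gaussian spots on the rim (inset by three spot
  sigmas so their tails stay inside the true outline; the ground-truth
  length is exactly `2·a·trajectory(t)`).
* **Nuclei windows** — rejection-sampled non-overlapping spots at
  controllable count, size and separation.  Spots are isotropic Gaussians
  by default; a flat-core profile (disc of radius `R` with a Gaussian
  edge) is available and is used wherever projected *area* is the
  measurand, because the thresholded area of a sharp-edged disc tracks
  `R²` the way real interphase nuclei do, whereas the area of a Gaussian
  spot under a local-mean threshold does not (the effective threshold
  level scales with spot size relative to the threshold window).
  Ground truth records each spot's half-maximum area, which scales as the
  squared size parameter by construction.
* **Pole-cell stacks** — `n` Gaussian blobs rejection-sampled in a ball,
  rotated in the `(z, x)` plane by a tilt angle with the same sign
  convention as the de-rotation operator, rendered with per-axis sigmas
  when voxels are anisotropic.
* **Staging tables** — 18 mean stage boundaries plus independent
  per-boundary Gaussian jitter, re-sorted to stay monotone.  The default
  mean table is invented but anchored on the qualitative timeline
  (62.5 h total; a long quiescent stage 5 of 4.5 h; 7.5 h germband
  retraction; germband elongation with a fast ~2 h phase and a slow
  ~5.5 h phase).

Noise is shot (Poisson) followed by additive Gaussian read noise, both
optional and on by default.  Signal-to-noise is quoted as spot amplitude
over the background noise SD, `A / sqrt(B + sigma_read²)`.

## Study conditions for the recovery experiments

Frozen in `embryostager.experiments`; the headline numbers they produce
are recomputed by `scripts/acceptance.py`:

* **Length**: 20 random single-frame embryos (a ∈ [150, 220] px,
  b ∈ [60, 100] px) noise-free, and 20 with noise at SNR 5–16 (nuclear
  and cytoplasmic intensity scale together 2:1, as both do with
  expression level and exposure in a real recording).  A 30-frame movie
  whose trajectory dips to 0.90 probes the normalized minimum, mirroring
  the length minimum near 90 % of the initial extent during dorsal
  closure.
* **Nuclei counts**: 20 windows, counts 10–60, sigma 3 px, SNR 5–15,
  minimum separation 10 px, placement margin 24 px; detection scales
  (2.5, 4.0) bracketing the effective blob sigma `sqrt(3² + 2²) ≈ 3.6`,
  detection threshold a quarter of the maximum response (appropriate for
  equal-brightness nuclei).  The error is summarized over all nuclei in
  the experiment; see *Limitations* for why isolated single-nucleus
  losses occur.
* **Division event**: flat-core nuclei of radius 10 px (edge 2 px;
  detection sigma `R/√2 ≈ 7`, consistent with the published pre-division
  LoG range 5–15), counts 10 → 40, radius and edge scaled by `1/√3` so
  the true projected area falls exactly three-fold; threshold windows
  15 → 10 as published; noise off (see *Limitations*).
* **Pole cells**: five stacks of 27 blobs (sigma 2 px, cluster radius
  16 px) tilted so the pipeline must de-rotate by −40°, −7°, +41°, +13°
  and 0°; LoG filter sigma and seeding scales matched to the blob size.
* **Tip kinematics**: annotations at 15-minute intervals emulating
  ~400 µm in the first two hours and ~100 µm over the next 5.5 h, with
  0.3 px lateral annotation jitter.
* **Staging variability**: eight datasets, boundary jitter SD 0.3 h
  everywhere except 2.0 h at the boundary opening stage 11; eight
  datasets at this contrast make the SD-peak location identifiable
  despite the sampling noise of an n-dataset sample SD (five datasets at
  five-fold contrast misplace it in a few percent of draws).

Problem sizes (20 frames/windows, 30-frame movies, five ~56³ stacks,
8 staging datasets) keep each experiment in the seconds-to-a-minute
range while leaving the recovered quantities stable across seeds.

## Numerical and degenerate-input behaviour

Invalid configurations (even mean-filter ranges, non-positive windows,
non-monotone stage boundaries, infeasible spot placements, embryos that
do not fit their frame) raise configuration errors naming the violated
constraint before any computation starts.  Blank frames raise
"embryo not found"; a movie frame failing mid-series is recorded as
missing with a warning and bridged by linear interpolation during
aggregation.  Signal-free windows produce empty segmentations with a
warning.  Stage intervals are half-open `[start, end)`: every time in
the span maps to exactly one stage, a query exactly at a boundary opens
the next stage, and the end of stage 17 is outside the span.  Normalized
stage durations divide by their own sum and therefore total 1 to within
the last unit of floating precision.  Rotation by 0° is an exact
identity; tilt/de-tilt round trips are exercised at interpolation
tolerance.

## Limitations

* The generator emulates geometry, counts and noise, not optics: there is
  no point-spread function, no light-sheet stripe artifacts, no
  multi-view fusion, no intensity attenuation with depth, and nuclei are
  rotationally symmetric.  Passing recovery tests therefore demonstrates
  the correctness and robustness of the measurement pipelines, not their
  accuracy on real recordings, which additionally face debris, uneven
  illumination and biological shape variation.
* On a *flat* noisy background, about half of all pixels exceed their own
  local mean, so the local-mean threshold speckles outside true objects.
  Counting is robust to this (objects exist only where a detected seed
  lies inside the mask), but two consequences remain: projected-area
  measurements on noisy synthetic backgrounds are meaningless (hence the
  division event runs noise-free), and very occasionally (~0.02 % per
  nucleus) a speckle chain bridges an interior nucleus to the window
  border, where the border-removal rule discards it.  Real images have
  structured backgrounds for which the first effect is milder.
* The measured post-division area ratio sits a few percent above the
  true 1/3 because the fixed 2 px smoothing inflates small nuclei
  relatively more than large ones — a bias shared with the original
  pipeline.
* Tip distances use straight segments between discrete annotations, not
  the arc along the dorsal surface.
* The timepoint-to-hours mapping of the original accession, the exact
  crop rectangles and the pre-rotation angles per dataset live with the
  data publication and are treated as user-supplied configuration.
  Normalized developmental time is referenced to the recorded span
  (start of stage 1 to hatching) — synthetic tables are always complete,
  so no separate observed-span mode is needed.
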