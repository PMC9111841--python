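# Methods

This note records how each stage of the pipeline works, the parameters
that matter, what the phantom generator does and does not emulate, and
the numerical choices made where the design was open.

## Rotation normalization

**Model.** The slide grid is orthogonal, so the distribution of strong
gradient directions, folded modulo 90°, has a single dominant peak at
the grid's rotation angle θ. The estimator builds a magnitude-weighted
histogram of Sobel gradient directions on the BT.601 luminance channel
(weights 0.299/0.587/0.114 — the raster's color space is assumed to be
ordinary 8-bit RGB), locates the dominant bin, refines it with circular
parabolic interpolation over the three bins around the maximum, and
returns the minimal correction: −θ* for θ* < 45°, 90° − θ* otherwise,
with the tie at exactly 45° resolved to +45° (arbitrary but fixed).

**Parameters.**

- `bin_width_deg` (default 1°): must divide 90 evenly; sub-bin accuracy
  comes from the parabolic interpolation, so 1° bins suffice.
- `magnitude_floor_quantile` (default 0.75): pixels whose gradient
  magnitude falls below this quantile are excluded, so weak root and
  background texture does not dilute the grid-edge orientations. The
  histogram could equally be count-based; magnitude weighting was chosen
  because edge strength is exactly the evidence that a pixel lies on a
  grid edge.
- `rotation_presmooth_sigma` (default 1.5 px): a light Gaussian blur
  applied before the Sobel pass *for angle estimation only*. Without
  it, the resampling staircase of a tilted edge concentrates gradient
  magnitude on axis-aligned runs and biases the estimate toward 0°/90°
  by up to ~3° at intermediate angles; with it the worst error over a
  dense sweep is ~0.25°.
- Refinement: because the estimator is most accurate near 0°, up to two
  residual passes re-estimate the angle on the provisionally deskewed
  image and fold the residual into the correction.

A histogram whose peak does not exceed twice the uniform level is
flagged unreliable (a texture-only or blank image); the pipeline then
skips deskewing rather than applying a garbage rotation.

**Conventions.** Coordinates are 0-based, x = column, y = row, origin
top-left; boxes are half-open. Angles are positive counter-clockwise in
x-right/y-up axes. Rotation uses bilinear resampling about the image
center, canvas preserved, corners filled with the per-channel median
color (a neutral stand-in for slide background).

## Intersection detection

On the deskewed image, the two edges of each vertical line produce two
peaks in the column-wise sum of |∂I/∂x| (and likewise horizontally).
The stages, with their parameters:

1. **Profiles** (`smoothing_sigma`, default 3 px): absolute-value
   gradients are summed so both edges project as positive peaks; the
   signed sums are kept alongside, because the *sign* at a peak says on
   which side of the edge the (darker) line body lies. A Gaussian
   smooth absorbs residual tilt of a fraction of a degree.
2. **Peak detection** (`peak_distance`, default 50 px): standard
   highest-first suppression — the tallest peak wins within the
   minimum-distance radius. Peaks below `min_peak_rel_height` (default
   0.25) of the tallest surviving peak are discarded: a genuine line
   edge projects over the full image extent and dwarfs bumps from root
   texture.
3. **Pairing** (`max_line_width_px`, default adaptive): consecutive
   peaks closer than the threshold become one line. With the physical
   1:4 width:pitch ratio, edge-pair gaps (≈ w) and inter-line gaps
   (≈ 3w) form two well-separated clusters; the adaptive threshold is
   placed at the largest multiplicative jump in the sorted gaps, which
   also recognizes the regime where every line contributed only one
   surviving edge (one cluster → nothing paired). Pairs must bracket a
   line body — for dark lines, a falling then a rising edge — which
   rejects pairings of edges belonging to different lines.
4. **Single-edge recovery** (`keep_single_edges`, default on): when a
   line's width is below the peak-suppression distance, one of its two
   edges is suppressed and the line survives as a lone peak. The lone
   edge is placed on the line side its polarity indicates, offset by
   half the consensus line width. That width comes from the median of
   properly paired lines when any exist, otherwise from a search for
   the width that makes the polarity-placed centers most evenly
   pitched. Dropping lone edges entirely is possible via config but
   would silently lose whole grid lines.
5. **Luminance refinement**: each line center is relocated to the
   centroid of the squared luminance dip (background median minus mean
   luminance along the line's axis) inside a window of ± pitch/3. This
   makes the final center independent of which edges survived; squaring
   the dip lets the deep line-body dip dominate the shallow dips of
   overlying root tissue. Lines converging onto the same dip are merged
   (closer than 0.4 × pitch — genuine neighbors are a full pitch apart).
6. **Lattice filter**: the grid is evenly pitched, so lines farther
   than 0.15 × pitch from the best-anchored lattice are spurious
   (aggregated root edges, bubble rims) and are dropped. The filter
   only acts when at least four lines are present and at least three
   fit the lattice.
7. **Boxes** (`box_half_extent`, default 75 px → 150 px boxes at the
   nominal 1008 × 756 working resolution; `min_clipped_area_frac`,
   default 0.5): one square box per line crossing, clipped to the
   image; boxes keeping less than half their nominal area are dropped —
   a partial crossing at the border is not a reliable sampling area.
   Box coordinates are reported in the *input* frame (centers mapped
   back through the inverse rotation); the deskewed frame's boxes and
   image are kept alongside, and classification crops are taken from
   the deskewed frame so the grid cross is axis-aligned.

Detection is fully deterministic for a fixed image and config.

## Classification

The classifier is deliberately two-part: a pluggable feature extractor
and a small head, so a pretrained CNN backbone can replace the built-in
extractor without touching anything else (`register_extractor`).

**Handcrafted extractor** (default, self-contained): a 4×4×4 joint RGB
histogram (normalized to unit mass; separates orange grid, blue-gray
tissue, dark stain, pale background) concatenated with ten
stain-morphology statistics — luminance mean/std, gradient mean/std,
dark-pixel fraction (luminance < 110), connected dark-component count
and mean size, component perimeter/area ratio, blue-dominant mid-tone
fraction, and mean gradient over the dark mask. The morphology block is
what separates vesicles (few large compact dark blobs) from arbuscules
(many small high-perimeter filament fragments). Patches are resampled
to 64 × 64 for feature computation; the histogram is resolution-
invariant and the morphology statistics are area-normalized.

**Heads.**

- SVM: RBF kernel with C = 1.0 and γ = 0.25, on standardized features.
- FC: a single fully-connected softmax layer trained with minibatch
  Adam — 20 epochs, batch 32, initial learning rate 1e-3 halved every
  5 epochs, weight decay 1e-5, cross-entropy loss, seeded shuffling.
  The learning rate is configurable; 1e-4 is the other defensible
  reading of the recipe this schedule follows, and both work on the
  test problems.

Labels outside {0, 1, 2, 3} are rejected; training with fewer than two
classes raises an error naming the missing classes. Models serialize
with joblib and reload prediction-identically.

**Augmentation**: horizontal and vertical reflections plus `n_crops`
random square crops (fraction 0.8 by default), all resized to 224 × 224
with bilinear interpolation, labels inherited, RNG seeded. About 60
augmented copies per source image turn a 5 000-patch dataset into a
300 000-patch one.

**Evaluation**: stratified k-fold cross-validation (default k = 5),
accuracy averaged over folds, confusion matrix (rows = true) summed
over folds so its row sums equal per-class counts. A class with fewer
members than k raises a stratification error.

## Colonization proportions

AC = N_a/(N_s − N_nr), VC = N_v/(N_s − N_nr). The negative count is
tallied and reported but appears in no formula. Design points:

- A zero denominator (all sampling areas rootless) yields an explicit
  undefined state, serialized as JSON `null` — reporting 0% colonization
  for a rootless image would be actively misleading.
- Fewer than 200 sampling areas triggers a warning, not a refusal; the
  manual protocol's sample-size floor should not block demonstrations.
- Multi-image quantification pools counts before dividing (per-image
  proportions are reported alongside); pooling matches a protocol that
  aggregates crossings over a sample's slides.
- A future "hyphae only" label would be counted with arbuscules; the
  four-class scheme already folds it there.

## Detection scoring

IoU uses half-open pixel boxes; zero-area boxes are rejected.
Predictions are matched to ground truth one-to-one by the assignment
maximizing total IoU (Hungarian algorithm; zero-overlap pairs never
match). Greedy best-first matching was considered and rejected: it
fails to attain the optimal assignment on a fraction of a percent of
random instances, and the matching is required to agree exactly with
exhaustive enumeration on small instances. Mean IoU is averaged over
ground truths with unmatched ground truths contributing zero; precision
at t is the fraction of *predictions* whose matched IoU strictly
exceeds t (recall: same over ground truths; both are reported since
either convention is defensible). No predictions → precision undefined,
flagged.

## Phantom generator

`generate_slide` renders: pale background (default RGB 238/234/226)
with unit Gaussian texture; the orange grid (230/140/40; line width
0.25 × pitch by default) drawn first — the grid is etched into the
slide; blue-gray root tissue (150/155/182) drawn over it at each
crossing whose label is not "no root", carrying the class morphology
(filled dark ellipses for vesicles, random-walk filament skeletons for
arbuscules, nothing extra for "negative"); optional artifacts; pixel
noise (σ = 2 by default); then the whole scene is rotated and the
ground-truth crossings are transformed through exactly the same map.
Line counts follow ⌊extent/pitch⌋ with the lattice centered in the
image. Determinism: one seed drives every random element, and identical
specs give bit-identical images.

Artifacts, mirroring the two failure modes a projection-profile
detector actually has:

- **Bubbles**: lightened disks with bright 3-px rims — circular
  high-gradient structures that can project as spurious peaks.
- **Jagged lines** (amplitude 8 px in the failure suite): a smooth
  meander (correlation length ~60 px) shared by both edges plus
  independent per-edge roughness. The meander moves the drawn line off
  its nominal position while the ground truth stays at the nominal
  lattice, so jagged slides must score strictly worse — this is the
  degradation the failure suite asserts.

**What the phantoms do not show.** Class morphologies are caricatures:
separable by construction, with none of the staining variability,
focus gradients, overlapping roots, debris, or illumination fields of
real micrographs. Tests passing on phantoms demonstrate that the
pipeline's logic is correct under its stated assumptions (orthogonal
dark-on-light grid, known width:pitch ratio, class-distinctive
morphology); they say nothing about classification accuracy on real
slides, which depends on training data from real annotated crossings.

## Problem sizes and tolerances

The shipped test and acceptance runs use: a 161-angle deskew sweep
(0.5° steps) on 1008 × 756 phantoms; 50 randomized detection slides
(rotation ±30°, pitch 180–320 px, width = 0.25 × pitch); 200 patches
per class for cross-validation; 1 000-case oracle comparisons for the
IoU and AC/VC formulas and 500 for matching; and ~30 training plus 6
evaluation slides for the end-to-end AC/VC check. These sizes keep a
full run in a few minutes on one core while leaving the statistical
checks (chance level 0.25 ± 0.05 on permuted labels at n = 800, etc.)
well-powered. Deskew accepts corrections only when the histogram peak
clears 2× the uniform level; detection IoU targets (recall 1.0 at
IoU > 0.5, mean IoU ≥ 0.85, precision ≥ 0.95 at IoU > 0.75) are the
package's phantom-scale analogues of field performance, not claims
about real data.
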