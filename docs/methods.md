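# Methods

This note documents the models, procedures and numerical choices behind
mammobalance: what each stage computes, which parameters matter, what the
phantom generator does and does not emulate, and the design decisions made
where the design was genuinely open.

## Problem setting

Mammography screening cohorts are heavily imbalanced: most breasts are
normal or benign, with benign:malignant ratios up to 19:1 in public FFDM
datasets (see `cohorts.py` for the published compositions the toolkit is
calibrated against).  Training a classifier on such data biases it toward
the majority class.  The toolkit implements the data-side treatments used
to study that bias — class weighting, under-sampling, over-sampling, and
synthetic-lesion insertion ("artifacting") — together with the image
preprocessing they operate on and the breast-wise evaluation protocol that
measures their effect.  Everything is exercisable on generated phantoms,
so the full pipeline is testable with no dataset download.

## Phantom mammograms

`generate_phantom` emulates FFDM *geometry*, not anatomy:

- **Breast**: a half-ellipse anchored to the chest-wall edge given by
  laterality, with semi-axes drawn from [0.40, 0.46]·H and
  [0.55, 0.65]·W, so the foreground occupies roughly 25–60% of the frame.
- **Texture**: base intensity 0.45 plus band-passed Gaussian noise
  (difference of σ = 4 px and σ = 16 px blurs, unit-normalised) scaled by
  0.3 × `density`.  This is the minimal structure the triangle threshold
  and the lesion blender need; there is no parenchymal pattern, no
  vessels, no skin line thickness.
- **Background**: Gaussian noise with mean 0.02, σ = 0.008, clipped at 0.
- **MLO views** add a triangular pectoral wedge (+0.12) hugging the top
  chest-side corner; it overlaps the ellipse, keeping the foreground a
  single connected component.
- **Label marker** (optional): a small bright disc (< 2% of pixels) in the
  background corner away from the chest wall, as burned-in markings
  appear on real films.
- A final σ = 0.8 px blur softens the skin line; intensities are clipped
  to [0, 1].  Everything is a pure function of the seed.

**Pixel spacing.** The default is 0.2 mm/px, making the default 512 × 408
frame a ~10 × 8 cm field — large enough to host millimetre-scale lesions
at realistic sizes.  Spacing is fully configurable; nothing downstream
assumes a particular value.  `preprocess` rescales the recorded spacing by
the resize factor, as resampling changes the physical sampling.

**Cohorts.** One patient = one breast pair; malignancy is assigned
breast-wise (each malignant breast is paired with a benign one while
supplies last), and patients are stratified by has-malignant status across
train/val/test with largest-remainder rounding, so a patient's images
never straddle splits.  Malignant phantoms are produced by inserting
synthetic lesions into a clean phantom; ground-truth annotations
(lesion kind, centre, support mask) are written as JSON/PNG sidecars.
Images are 16-bit PNG; the manifest stores paths relative to the cohort
directory, so regenerating a cohort with the same spec is byte-identical.

What passing tests on phantoms do **not** show: robustness to real tissue
texture, vendor intensity curves, pectoral-muscle segmentation errors, or
real lesion appearance.  The phantoms validate plumbing, geometry and
statistical contracts, not clinical performance.

## Preprocessing chain

`preprocess` = triangle threshold → largest 4-connected component →
orient left → crop/resize/pad → in-breast histogram equalisation.

- **Triangle threshold** operates on the 256-bin histogram: a line runs
  from the (first) peak bin to the farthest non-empty bin on the longer
  tail (right tail on ties); the threshold is the bin maximising the
  perpendicular distance to that line, smallest index on ties.  Foreground
  is `img > (bin + 1)/256`.
- **Breast extraction** keeps the largest 4-connected component and zeroes
  everything else, which removes label markings.
- **Orientation** flips horizontally iff the mask centroid lies in the
  right half — metadata-free, so wrong or missing laterality tags cannot
  mis-orient an image.
- **Geometry**: rows and columns are cropped to the mask's tight bbox, the
  crop is scaled (bilinear; anti-aliased when downscaling) so its height
  equals the target, the right side is zero-padded to a square; should the
  scaled width exceed the target (very wide breasts) columns are
  centre-cropped.  Coordinates are 0-based, row-major, bboxes half-open.
- **Normalisation** is histogram equalisation computed over in-mask pixels
  only (256 bins), mapping monotonically onto [0, 1]; the background stays
  exactly 0.  A constant in-mask image maps to 0.5.

Three numerical choices keep the chain stable under re-application
(running `preprocess` twice changes pixels by < 2/256 in sup-norm):

1. equalised in-mask values are floored at 1/512 — half a bin — so the
   breast support stays distinguishable from the exact-zero background
   (the minimum still maps to 0 within one bin width);
2. the mask is resized with bilinear *coverage* (> 0) rather than
   nearest-neighbour, so a one-pixel breast tip survives downsampling
   instead of vanishing and shifting the crop by a row;
3. on an input already flagged normalised, the chain binarises at zero
   (its own background convention) instead of re-estimating a threshold.

## Lesion synthesis

**Spiculated masses.**  The contour is a log-normal radial process on the
circle: r(θ) = R·exp(z(θ) − σ²/2), where z is a zero-mean wrapped Gaussian
process with squared-exponential correlation (length scale
`angular_corr_deg`, default 30°) sampled at 360 angles via an
eigendecomposition of the wrapped covariance.  The −σ²/2 drift cancels the
log-normal mean, so E[r] = R exactly; σ = 0 gives a perfect circle, and
the contour is star-shaped (single-valued radius) and strictly positive by
construction.  The filled contour gets a half-cosine radial falloff with
peak `contrast` (default 0.8).  Spicules grow outward from the contour:
`n_spicules` (default 12) roots at uniform random angles, stepping 2 px at
a time with 10° Gaussian angular jitter, length `spicule_len_mm` (default
2 mm, ±20%); each step below the depth cap spawns a branch with
probability `branch_prob` at 20–40° to the parent with a 0.6× length
budget.  Width (2.5 px at the root) and intensity taper linearly to zero
at the tip.  Defaults give a ~6 mm core with a ~10 mm stellate extent —
a small, screening-relevant mass.

**Microcalcification clusters.**  `n_calcs` (default 8) elliptical
deposits with equivalent diameters drawn uniformly from 0.25–1 mm — the
size band in which clustered calcifications suggest malignancy — scattered
uniformly inside a convex elliptical cluster region (default radius 4 mm).
Each deposit's brightness profile is a steep super-Gaussian
exp(−ln2·m⁴) whose half-maximum contour sits exactly at the nominal
equivalent diameter (axis ratio 0.7–1 preserves the equivalent diameter);
the profile is truncated at m = 2 so supports are finite.  Spacings at
which the smallest deposit would be sub-pixel are rejected as a
configuration error — sub-millimetre calcifications physically require
sub-quarter-millimetre sampling.

Measured diameters (tests, acceptance script) come from marching-squares
contours at half maximum; the shoelace area of the inscribed polygon is
corrected by the regular-polygon relation A = (n/2)R²sin(2π/n), without
which a 2.5-px blob reads ~8% small.

**Architectural distortions.**  An inverse-mapped swirl: the output pixel
at polar offset (ρ, φ) from the centre samples the input at
φ + strength·exp(−ρ/r_eff), r_eff = radius·ln 2/5, with bilinear
interpolation.  strength = 0 is the identity, the centre is a fixed point,
and the twist decays below half a pixel of arc displacement at a support
radius found numerically (the closed form involves the Lambert W
function).  The implementation is cross-checked in the tests against
scikit-image's swirl, which uses the same mapping.

**Insertion.**  Mass and calcification patches blend additively in
normalised intensity space, `out = clip(img + alpha·intensity·gain, 0,
1)` with gain 0.35; distortions warp in place but only within their
support disc, so in all cases pixels outside the recorded support are
bit-identical to the input.  `artifact_image` inserts k ∈ {1, 2, 3}
lesions with kinds drawn from a mass/calc/distortion mixture of
0.5/0.3/0.2 (masses dominate presentations, distortions are rarest; the
mixture is configurable).  Sites are uniform over the breast mask eroded
by the patch radius plus a 2 mm margin (20 px at the 0.1 mm/px reference
spacing), and the k patches are placed jointly — largest first, with
restarts — until their supports are pairwise disjoint; purely sequential
placement can dead-end on small breasts even when an arrangement exists.
Insertion canonically operates on preprocessed images (lesions are
inserted at training-batch construction, i.e. after normalisation), but
accepts any [0, 1]-intensity benign image; cohort generation uses it on
raw phantoms.  Inserting into an already-malignant image is a contract
violation: it could not change the class.

## Imbalance treatments

- **Class weighting**: w_minority = n_majority/n_minority over the
  training split, w_majority = 1, stored as an exact rational.  Weights
  are global: with batch size 8 a per-batch ratio can never exceed 7
  (exhaustively enumerated in `max_batch_minority_weight`), which cannot
  balance a 19:1 cohort.
- **Under-sampling**: the majority class of one split is sampled down to
  the minority count once, before training — a fixed subset, not
  re-drawn per epoch.  At 19:1 this discards ~90% of the training data.
- **Over-sampling epochs**: batches are half unseen-majority (each
  majority record appears exactly once per epoch) and half minority drawn
  with replacement; the final batch may be short, keeping its halves
  balanced — dropping records would break the exactly-once contract.
- **Artifacted epochs**: each batch holds B/2 benign as-is, 2 real
  malignant (with replacement — the real minority is over-sampled), and
  B/2 − 2 artifact directives referencing benign records already in the
  batch, with k uniform on {1, 2, 3} and a stored per-directive seed for
  replay.  At B = 8 that is the 4 + 2 + 2 composition; the epoch is one
  pass of the benign records through the as-is slots, shuffled per seed.
  `realize_batch` materialises directives; artifacted copies get a
  derived breast id (`…+art`) since they are synthetic breasts.
- **Minority pacing**: batches are reassigned to the five 20% windows of
  the epoch greedily (largest malignant count first, least-loaded window),
  equalising real-malignant exposure per window to ±1 whenever the
  per-batch counts make that feasible — which the planners above, with
  constant per-batch counts, always do.
- **Augmentation**: vertical flip (p = 0.5), rotation ±10°, zoom ±10%,
  integer translation strictly below 100 px per axis, and 0–3 rectangular
  patches (≤ 200 px side) inpainted with their local mean.  The zoom range
  is a default choice; flip/translation/rotation limits follow the
  training protocol the treatments are designed for.

All planners are pure functions of (index, seed) and serialise to JSONL.

## Evaluation

Per-view scores are averaged into one score per breast (malignancy may be
visible in only one of CC/MLO, and the breast is the clinical unit); a
breast is malignant if any of its images is.  AUC-ROC is computed as the
Mann–Whitney statistic from midranks (ties count half), so it is invariant
under monotone score transforms.  Se/Sp are exact ratios at the operating
point (score ≥ threshold → malignant; threshold ties predict malignant);
a zero denominator yields a missing value, not an exception.  MCC follows
the standard confusion-matrix form with the 0-on-zero-denominator
convention — needed so the all-predicted-benign regime of extreme
imbalance reports near-zero correlation rather than crashing.  Standard
errors are the standard deviation of each metric over 1000 bootstrap
resamples of *breasts* (the resampling unit matches the metric unit);
resamples that lose a class are redrawn, capped at 10× the resample
count.  The report carries per-class 20-bin histograms of breast scores,
each normalised to sum to 1 so shapes are comparable across classes
regardless of imbalance.

The **mean-intensity baseline** (per-image mean over in-breast pixels,
min–max rescaled across the evaluated cohort; a singleton or constant
cohort scores 0.5) is a deliberately trivial stand-in for a trained
classifier in end-to-end tests.  On normalised images equalisation makes
the clean in-breast mean nearly deterministic (≈ 0.5), while inserted
lesions add intensity on top — so the baseline separates artifacted from
clean breasts; on raw images it segments the breast first.  Distortions
add no intensity, so swirl-only malignant images score at chance for this
baseline — a property of the baseline, not of the lesions.

## Problem sizes used in tests

The suite runs phantoms at 320 × 256 to 512 × 408 px; the end-to-end
smoke test generates a 200-image 19:1 cohort at 0.125 mm/px and
preprocesses to 256 × 256.  That spacing models a small (~6.4 cm)
compressed breast: at a 256-px target the post-resize spacing must stay
below 0.25 mm/px for sub-millimetre calcifications to remain renderable.
Monte-Carlo checks use 1000–2000 draws (contour mean, calcification band,
oracle equivalences), enough to pin 2% tolerances.

## Known limitations

- Phantom tissue is stationary band-passed noise; no parenchymal
  structure, so texture-sensitive failure modes are untested.
- No pectoral-muscle removal and no vendor intensity calibration (VOI
  LUTs) — out of scope of the chain.
- The swirl leaves intensity statistics unchanged, so intensity-only
  scorers are blind to distortions by design.
- Lesion blending is additive with a global gain; real lesion contrast
  depends on tissue thickness and beam physics.
- The 2-D contour model reproduces the projection statistics of a
  stochastic Gaussian-sphere mass, not its 3-D structure.
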