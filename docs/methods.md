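# Methods

## Sharpness: variance of the Laplacian

The focus measure is the population variance (divide by *N*) of the
discrete Laplacian response. Conventions, all of which affect absolute
score values and are therefore fixed contracts of this package:

* **Grayscale**: ITU-R BT.601 luma, 0.299 R + 0.587 G + 0.114 B. Camera
  pipelines and common imaging libraries default to this weighting, so
  scores are comparable with other tools.
* **Kernel**: the 4-connected 3 × 3 stencil [[0,1,0],[1,−4,1],[0,1,0]]
  with replicate (edge-clamp) borders, the most common discrete form of
  the operator. Images smaller than the kernel are rejected.
* **No resizing**: scores are computed at native resolution. The
  variance of the Laplacian is strongly resolution-dependent, so scores
  from devices with different sensors are not directly comparable;
  callers who need that comparability should downscale consistently
  before scoring.

Useful identities that the test suite verifies: the score is invariant
to adding a constant intensity (the Laplacian annihilates constants),
scales as *a²* under intensity scaling by *a*, is zero exactly when the
response is constant over the region, and decreases strictly with
Gaussian blur on checker scenes.

## Sticker detection

The detector implements a minimal pipeline consistent with "find a
rectangle of sufficient size":

1. Sobel gradient magnitude of the luma image, thresholded at
   max(Otsu, 0.02 on the [0,1] scale). A featureless image (maximum
   gradient below the floor) short-circuits to "not found".
2. Morphological closing (disk radius 2) and hole filling turn the
   sticker's dense patch-edge lattice into a solid blob. Defocus widens
   the lattice gaps, so on failure the closing radius escalates to 4,
   then 6; sharp scenes resolve at radius 2, where corner estimates are
   tightest. The cascade is deterministic.
3. Each connected component is fitted with its convex hull's
   minimum-area rotated rectangle (shapely). A candidate must fill ≥80%
   of its rectangle (rectangularity — an ellipse fills ~78.5%, so smooth
   blobs fail), the rectangle must cover ≥ `min_area_fraction` of the
   frame (default 0.02) and have aspect ratio ≤ `max_aspect_ratio`
   (default 1.3; the sticker is square).
4. With `grid_check` on (default), the candidate is rectified by a
   projective transform to a 96 × 96 square, trimmed by an 8% margin,
   divided 6 × 6, and the standard deviation of the 36 cell means must
   reach `grid_min_std` (default 10 gray levels). Mutually distinct
   patches give a large spread; skin and wound regions are smooth and
   fail. Misalignment from the sticker's white border only mixes
   neighboring patches and does not destroy the spread, so the check is
   robust without knowing the exact border width.

The fitted rectangle is inset by 1.5 px per side before corners and the
ROI mask are emitted: the thresholded edge band straddles the physical
sticker boundary, biasing the blob outward by about the band's
half-width, and the inset also keeps the strong sticker/skin boundary
edge from inflating the ROI sharpness. On unblurred synthetic scenes the
detected corners land within ~1 px of ground truth and the detected-ROI
score within 10% of the ground-truth-ROI score.

Among candidates that pass every check, the largest rectangle wins, with
deterministic tie-breaks on the top-left corner position. When a
candidate fails *only* the size threshold, the result records that a
"too small" candidate existed, which the gate reports as
`checker_too_small` instead of `checker_not_found`.

## Quality gate

Pass requires detection *and* CCS strictly greater than
`sharpness_threshold` ("exceeding" is read as a strict inequality). The
default threshold of **1825** was calibrated once on the synthetic
fixture suite as the midpoint between the median CCS of 20 seeded
unblurred scenes (≈3612) and the same scenes at blur σ = 4 (≈39);
`scripts/calibrate_threshold.py` reproduces the number. The threshold is
a property of scene statistics, scale and optics — deployments on real
imagery must recalibrate it on their own device; the config file exposes
it for exactly that reason.

## Study metrics

* **CCDR** is the pooled-count ratio detected/collected. The per-group
  CCDR is computed from pooled counts, *not* as the mean of per-patient
  ratios (the two differ when patients contribute unequal image counts).
* **Quantiles** use linear interpolation between order statistics
  (NumPy's default), applied to CCS values of images where a sticker
  region was available.
* **Per-group CCS comparison** is exposed both ways the study uses it:
  pooled per-image distributions and per-patient medians; the report
  contains a rank-sum test for each, named distinctly.
* **Compliance** counts distinct calendar dates with ≥1 saved image
  (multiplicity within a day does not count) over 16 assigned days,
  capped at 1.
* **Duration outliers**: remove d when |d − median| > 3 × 1.4826 × MAD,
  MAD = median(|dᵢ − median|). The 1.4826 factor makes the scaled MAD
  estimate the standard deviation under normality, the convention of
  mainstream statistics environments. With all-equal inputs the MAD is
  zero and only exact-median values survive — all of them, so nothing is
  removed. The filter is not idempotent in general (the kept subset has
  its own median and MAD); the report applies it once, within patient.
* **Rank-sum test**: two-sided. For untied samples with both sizes ≤ 25
  the p-value comes from the exact null distribution of the rank sum,
  computed by dynamic programming over subset rank sums — the same
  small-sample switch mainstream implementations make, and necessary
  because the normal approximation can be off by ~0.04 at n = 3–7.
  Otherwise: midranks for ties, tie-corrected variance, 0.5 continuity
  correction. The reported statistic is always the standardized rank sum
  of the first sample, so swapping samples flips its sign and preserves
  the p-value.
* **Duration trend**: ordinary least squares of duration on assessment
  index; degenerate designs (all indices equal) are an error.

## Synthetic data

`render_scene` emulates the fixed-holder acquisition geometry: constant
sticker scale (default ~7% of a 480 × 360 frame), in-plane rotation
only, Gaussian defocus, a global illumination offset, and additive
Gaussian sensor noise clipped to [0, 255]. The 36-patch palette is a
documented stand-in (24 classic calibration colors plus 12 skin/wound
shades); the commercial sticker's exact palette is not public, and
nothing downstream depends on specific colors — only on patches being
locally uniform and mutually distinct. Not modeled: perspective
distortion, specular highlights, shadows, demosaicing and compression
artifacts, photo-realistic wound appearance. Passing detection tests on
these scenes therefore demonstrates the pipeline's correctness and its
behavior under blur/noise/pose variation, not field performance on real
skin.

`generate_cohort` samples a two-arm cohort at the study's conditions by
default: 8 feedback / 7 basic patients, 16 assigned assessment days,
1 + Poisson(0.8) images per performed day (~25 images per patient),
detection probabilities 0.96 / 0.86, usability probabilities
0.90 / 0.85, and per-image CCS drawn log-normally — location set by the
group medians 894 / 700 and log-scale σ solved from the printed
interquartile ranges via σ = ln(q75/q25) / (2 · 0.6745), giving 0.253 /
0.339. The log-normal guarantees positivity and matches the reported
median/IQR summaries; the true per-image CCS law is unknown. Durations
follow 52 − 0.5 · day + N(0, 8²) seconds (floored at 5 s), attached to
the first image of each performed day. Day-skipping is Bernoulli with a
per-patient probability drawn from a Beta distribution centered on the
group mean (0.23 feedback / 0.08 basic, concentration 12), reproducing
compliance medians near 0.77 / 0.94.

## Problem sizes and numerical choices

The test and acceptance suites run 100-scene detection suites at
480 × 360, 20-scene blur ladders, and 100 cohort replicates — sizes at
which every statistical bound checked (recall ≥95%, false positives
≤5%, rank-sum power ≥90% at α = 0.001) holds with a comfortable margin
under the binomial sampling noise at n = 100. Floating-point
comparisons use relative tolerance 1e-6 where exactness is not
guaranteed; the Laplacian against its brute-force oracle, and manifest
round-trips, are exact.

## Known limitations

* The detector assumes one sticker per scene; multi-sticker scenes
  return the largest.
* Corner accuracy degrades at heavy blur (the escalated closing radius
  rounds corners); blurred captures are gated out anyway.
* The sharpness threshold and `grid_min_std` are calibrated on the
  synthetic scenes and must be recalibrated per device for real use.
* Quality is judged on the sticker region only; a scene with a sharp
  sticker but a wound outside the focal plane would pass.
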