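# woundqc

Acquisition-time quality control for wound photographs, built for remote
self-documentation of chronic wounds (for example digital ulcers in
systemic sclerosis, where patients photograph their own fingers at home).
Each capture includes a square 30 × 30 mm color reference sticker with 36
color patches beside the wound. `woundqc` answers, at the moment of
capture, the two questions a tele-wound workflow needs answered before an
image is worth uploading: *is the reference sticker visible*, and *is the
image in focus* — and then computes the quality and feasibility metrics a
two-arm study of such a workflow reports.

## What it computes

**Sharpness.** An image's focus is scored as the variance of the
Laplacian: for a grayscale image *I*, the response *L = I ∗ k* with the
4-connected stencil *k* = [[0,1,0],[1,−4,1],[0,1,0]], and the score is
Var(*L*) over a region of interest. Sharp edges and fine texture produce
large second-derivative excursions; defocus blur suppresses them, so the
variance falls monotonically with blur. Restricting the variance to the
sticker region — the **color checker sharpness (CCS)** — makes scores
comparable across patients, because the sticker's content is constant
while wounds are not.

**Detection.** The sticker is localized by its rectangular morphology:
edge map → morphological solidification → minimum-area rotated rectangle
per connected component, filtered by a size threshold (minimum area
fraction of the frame), an aspect-ratio bound, and a 6 × 6 patch-grid
structure check. The **color checker detection ratio (CCDR)** of an image
set is the fraction of images in which the sticker was detected.

**Quality gate.** A capture passes when the sticker is found *and* its
CCS strictly exceeds a configurable threshold; otherwise the user is told
to retake, with reasons `checker_not_found`, `checker_too_small` or
`blurry`.

**Study metrics.** Per-group and per-patient CCDR, CCS quartiles and
subjective-usability ratios; protocol compliance (performed assessment
days / 16 assigned days, capped at 1); duration-outlier removal beyond 3
scaled median absolute deviations from the median; a two-sided Wilcoxon
rank-sum comparison between groups; and an OLS duration trend over
assessment index.

Because no real patient images are distributable, the package ships a
deterministic generator of wound scenes (background, elliptical wound
blob, rendered 36-patch sticker at a known pose, Gaussian blur /
illumination / noise) with exact ground truth, and of synthetic two-arm
cohorts with study-scale parameters.

## Worked example

```python
from woundqc import (QualityConfig, assess_quality, detect_checker,
                     checker_roi_sharpness)
from woundqc.synthetic import SceneSpec, render_scene

image, truth = render_scene(SceneSpec(checker_center=(350.0, 140.0), seed=11))
det = detect_checker(image)
print(det.found, round(det.area_fraction, 4))      # True 0.0687
print(round(checker_roi_sharpness(image, det).value, 1))  # 2778.3

decision = assess_quality(image, QualityConfig(sharpness_threshold=1825.0))
print(decision.passed, sorted(decision.reasons))   # True []
```

The sticker is found covering ~6.9% of the frame, its CCS of ≈2778 (in
squared intensity units) exceeds the default threshold of 1825, and the
capture passes. Rendering the same pose with `blur_sigma=6.0` drops the
CCS to ≈36 and the decision to `False ['blurry']`.

From a shell, the same workflow is:

```bash
woundqc synth scene --out scenes/ --n 10 --blur 0,2 --seed 7
woundqc batch scenes/ --out decisions.csv
woundqc synth cohort --out manifest.csv --seed 7
woundqc report --manifest manifest.csv --out report.json
```

`report.json` contains per-group CCDR / CCS quartiles / usability, the
per-patient table, compliance ratios, rank-sum p-values and duration
trends.

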