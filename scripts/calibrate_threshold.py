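"""One-off calibration of the default sharpness threshold.

Renders 20 seeded fixture scenes at blur sigma 0 and sigma 4, scores the
detected sticker ROI, and prints the midpoint between the two median CCS
values. The result is frozen as gate.DEFAULT_SHARPNESS_THRESHOLD.
"""
import numpy as np

from woundqc import checker_roi_sharpness, detect_checker
from woundqc.synthetic import SceneSpec, render_scene

scores = {0.0: [], 4.0: []}
for seed in range(20):
    rng = np.random.default_rng(seed)
    center = (float(rng.uniform(180, 380)), float(rng.uniform(110, 240)))
    rot = float(rng.uniform(-20, 20))
    for sigma in (0.0, 4.0):
        img, _ = render_scene(SceneSpec(
            checker_center=center, checker_rotation=rot,
            blur_sigma=sigma, seed=seed))
        det = detect_checker(img)
        if det.found:
            scores[sigma].append(checker_roi_sharpness(img, det).value)

m0 = float(np.median(scores[0.0]))
m4 = float(np.median(scores[4.0]))
print(f"sigma=0 median CCS {m0:.1f} over {len(scores[0.0])} scenes")
print(f"sigma=4 median CCS {m4:.1f} over {len(scores[4.0])} scenes")
print(f"midpoint threshold {(m0 + m4) / 2:.1f}")
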