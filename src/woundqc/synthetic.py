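"""Deterministic synthetic wound scenes and study cohorts.

Real patient wound photographs from remote self-documentation studies are
not publicly deposited, so this module renders controllable stand-ins:

* :func:`render_scene` draws a skin-toned background, an optional
  elliptical wound blob, and an optional square color-reference sticker —
  a 6x6 grid of 36 distinct color patches inside a thin white border —
  at a specified position, size and in-plane rotation, then applies
  Gaussian defocus blur, a global illumination offset, and additive
  Gaussian sensor noise. Ground-truth sticker corners and the ROI mask
  are returned alongside the pixels.

* :func:`generate_cohort` samples per-image assessment records for a
  two-arm remote-imaging study (a "feedback" arm receiving acquisition-
  time quality feedback and a "basic" arm without it): per-group checker
  detection probabilities, log-normal sharpness scores, subjective
  usability labels, per-assessment durations with a linear time trend,
  and per-patient day-skipping for compliance analysis.

Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .imaging import RegionOfInterest, WoundImage
from .metrics import AssessmentRecord

__all__ = [
    "SceneSpec",
    "SceneGroundTruth",
    "GroupParams",
    "CohortSpec",
    "render_scene",
    "generate_cohort",
    "detection_suite",
    "order_corners",
    "CHECKER_PALETTE",
]

# 36-patch palette: 24 classic photography calibration colors plus 12
# skin- and wound-specific shades. The commercial sticker's exact palette
# is proprietary; this fixed stand-in preserves the structural property
# that matters for detection — mutually distinct, locally uniform patches.
CHECKER_PALETTE: Tuple[Tuple[int, int, int], ...] = (
    # classic calibration colors
    (115, 82, 68), (194, 150, 130), (98, 122, 157), (87, 108, 67),
    (133, 128, 177), (103, 189, 170), (214, 126, 44), (80, 91, 166),
    (193, 90, 99), (94, 60, 108), (157, 188, 64), (224, 163, 46),
    (56, 61, 150), (70, 148, 73), (175, 54, 60), (231, 199, 31),
    (187, 86, 149), (8, 133, 161), (243, 243, 242), (200, 200, 200),
    (160, 160, 160), (122, 122, 121), (85, 85, 85), (52, 52, 52),
    # skin shades
    (255, 224, 196), (241, 194, 167), (224, 172, 138), (198, 134, 102),
    (161, 102, 77), (110, 70, 52),
    # wound shades (granulation, slough, necrosis, erythema)
    (188, 48, 38), (219, 112, 91), (226, 191, 127), (242, 222, 180),
    (90, 38, 32), (48, 24, 20),
)

_GRID = 6  # patches per side
_BORDER_FRACTION = 0.06  # white sticker margin, fraction of side length


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered wound scene.

    The defaults emulate a phone held in a fixed holder over a finger:
    the sticker sits beside the wound, roughly 10% of the frame area,
    with mild sensor noise.
    """

    image_size: Tuple[int, int] = (480, 360)  # (width, height)
    checker_center: Tuple[float, float] = (330.0, 170.0)
    checker_side: float = 110.0
    checker_rotation: float = 8.0  # degrees, counterclockwise
    blur_sigma: float = 0.0
    illumination_offset: float = 0.0
    noise_sd: float = 2.0
    include_checker: bool = True
    include_wound_blob: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.image_size
        if w < 8 or h < 8:
            raise ValueError("image must be at least 8x8")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma and noise_sd must be nonnegative")
        if self.include_checker:
            corners = _checker_corners(self)
            if (corners[:, 0].min() < 0 or corners[:, 1].min() < 0
                    or corners[:, 0].max() > w - 1 or corners[:, 1].max() > h - 1):
                raise ValueError("checker does not fit inside the frame")


@dataclass(frozen=True)
class SceneGroundTruth:
    """Exact sticker geometry of a rendered scene."""

    corners: Optional[np.ndarray]  # (4, 2) float, clockwise from top-left
    area_fraction: Optional[float]
    roi: Optional[RegionOfInterest]
    blur_sigma: float


def order_corners(corners: np.ndarray) -> np.ndarray:
    """Canonically order 4 quadrilateral corners.

    Clockwise in image coordinates (y down), starting from the corner
    nearest the image origin (smallest x + y). Shared between generator
    ground truth and the detector so corner errors compare like to like.
    """
    pts = np.asarray(corners, dtype=np.float64).reshape(4, 2)
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    # increasing angle is clockwise when y points down
    pts = pts[np.argsort(ang)]
    start = int(np.argmin(pts.sum(axis=1)))
    return np.roll(pts, -start, axis=0)


def _checker_corners(spec: SceneSpec) -> np.ndarray:
    half = spec.checker_side / 2.0
    theta = np.deg2rad(spec.checker_rotation)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    local = np.array([[-half, -half], [half, -half], [half, half], [-half, half]])
    return order_corners(local @ rot.T + np.asarray(spec.checker_center))


def _skin_background(w: int, h: int) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    base = np.array([205.0, 168.0, 148.0])
    # gentle diagonal illumination falloff so the background is not flat
    shade = 1.0 - 0.12 * (xx / max(w - 1, 1) + yy / max(h - 1, 1)) / 2.0
    return base[None, None, :] * shade[..., None]


def _add_wound_blob(img: np.ndarray, w: int, h: int) -> None:
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = 0.32 * w, 0.55 * h
    ax, ay = 0.16 * w, 0.11 * h
    d2 = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
    # soft-edged reddish ulcer with a darker core
    alpha = np.clip(1.2 - d2, 0.0, 1.0)
    wound = np.array([165.0, 52.0, 48.0])
    core = np.clip(0.5 - d2, 0.0, 1.0)
    img += alpha[..., None] * (wound[None, None, :] - img)
    img += core[..., None] * np.array([-60.0, -15.0, -12.0])[None, None, :]


def _paint_checker(img: np.ndarray, spec: SceneSpec) -> np.ndarray:
    """Draw the sticker; returns the boolean inside-sticker mask."""
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = np.deg2rad(spec.checker_rotation)
    cx, cy = spec.checker_center
    # map pixel centers into the sticker's local frame, u,v in [0, side]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(theta) + dy * np.sin(theta) + spec.checker_side / 2.0
    v = -dx * np.sin(theta) + dy * np.cos(theta) + spec.checker_side / 2.0
    side = spec.checker_side
    inside = (u >= 0) & (u < side) & (v >= 0) & (v < side)

    margin = _BORDER_FRACTION * side
    patch_pitch = (side - 2 * margin) / _GRID
    in_grid = (inside & (u >= margin) & (u < side - margin)
               & (v >= margin) & (v < side - margin))

    img[inside] = (250.0, 250.0, 248.0)  # white sticker stock
    col = np.clip(((u - margin) / patch_pitch).astype(int), 0, _GRID - 1)
    row = np.clip(((v - margin) / patch_pitch).astype(int), 0, _GRID - 1)
    palette = np.asarray(CHECKER_PALETTE, dtype=np.float64)
    idx = row * _GRID + col
    img[in_grid] = palette[idx[in_grid]]
    return inside


def render_scene(spec: SceneSpec) -> Tuple[WoundImage, SceneGroundTruth]:
    """Render one scene and its exact ground truth.

    Returns
    -------
    (WoundImage, SceneGroundTruth)
        The 8-bit RGB image and the sticker corners / area fraction /
        ROI mask (all ``None`` when ``include_checker`` is false).
        Identical spec (including seed) gives bit-identical pixels.
    """
    w, h = spec.image_size
    img = _skin_background(w, h)
    if spec.include_wound_blob:
        _add_wound_blob(img, w, h)

    corners = None
    area_fraction = None
    roi = None
    if spec.include_checker:
        mask = _paint_checker(img, spec)
        corners = _checker_corners(spec)
        area_fraction = float(spec.checker_side**2 / (w * h))
        roi = RegionOfInterest(mask)

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    img = img + spec.illumination_offset
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    image = WoundImage(pixels)
    truth = SceneGroundTruth(
        corners=corners, area_fraction=area_fraction, roi=roi,
        blur_sigma=spec.blur_sigma,
    )
    return image, truth


def detection_suite(n_scenes: int, seed: int,
                    include_checker: bool = True) -> List[SceneSpec]:
    """Seeded scene specs for detector recall / false-positive evaluation.

    Recall scenes carry a sticker at 4%-10% of the frame (comfortably
    above a 2% size threshold), blur sigma drawn from {0, 0.5, 1} and
    moderate sensor noise; false-positive scenes are identical but
    checker-free (wound blob and background only).
    """
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_scenes):
        side = float(rng.uniform(85.0, 132.0))  # area fraction 0.042-0.10
        margin = side / np.sqrt(2.0) + 2.0
        specs.append(SceneSpec(
            checker_center=(float(rng.uniform(margin, 480 - margin)),
                            float(rng.uniform(margin, 360 - margin))),
            checker_side=side,
            checker_rotation=float(rng.uniform(-25.0, 25.0)),
            blur_sigma=float(rng.choice([0.0, 0.5, 1.0])),
            noise_sd=3.0,
            include_checker=include_checker,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return specs


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class GroupParams:
    """Per-arm sampling parameters for synthetic cohorts.

    Defaults mirror the study conditions of an 8-week remote digital-ulcer
    documentation protocol: checker detection probability per image, a
    log-normal sharpness law (median on the raw scale, sigma on the log
    scale), probability an image is subjectively usable, and the mean
    probability a scheduled assessment day is skipped.
    """

    n_patients: int
    detection_prob: float
    ccs_median: float
    ccs_log_sigma: float
    usable_prob: float
    skip_prob: float

    def __post_init__(self) -> None:
        for p in (self.detection_prob, self.usable_prob, self.skip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.ccs_median <= 0 or self.ccs_log_sigma < 0:
            raise ValueError("invalid sharpness law")


def _sigma_from_iqr(q25: float, q75: float) -> float:
    # log-normal: q75/q25 = exp(2 * z_0.75 * sigma), z_0.75 = 0.6744898
    return float(np.log(q75 / q25) / (2 * 0.6744897501960817))


#: Study-condition defaults: 8 feedback vs 7 basic patients; detection
#: 0.96 vs 0.86; sharpness medians 894 vs 700 with spread matched to the
#: interquartile ranges 710-999 and 549-867; usability 0.90 vs 0.85.
DEFAULT_FEEDBACK = GroupParams(
    n_patients=8, detection_prob=0.96, ccs_median=894.0,
    ccs_log_sigma=_sigma_from_iqr(710.0, 999.0), usable_prob=0.90,
    skip_prob=0.23,
)
DEFAULT_BASIC = GroupParams(
    n_patients=7, detection_prob=0.86, ccs_median=700.0,
    ccs_log_sigma=_sigma_from_iqr(549.0, 867.0), usable_prob=0.85,
    skip_prob=0.08,
)


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic two-arm cohort specification.

    ``assessments_per_patient`` is the number of protocol-assigned
    assessment days (every third day over 8 weeks = 16). On each
    performed day a patient takes 1 + Poisson(``extra_images_mean``)
    images, reproducing the ~25 images per patient observed when some
    days yield several shots. Durations follow
    ``intercept + slope * day_index + N(0, noise_sd)`` seconds, attached
    to the first image of each performed day.
    """

    feedback: GroupParams = DEFAULT_FEEDBACK
    basic: GroupParams = DEFAULT_BASIC
    assessments_per_patient: int = 16
    extra_images_mean: float = 0.8
    duration_intercept: float = 52.0
    duration_slope: float = -0.5
    duration_noise_sd: float = 8.0
    skip_concentration: float = 12.0  # Beta concentration for per-patient skip prob
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assessments_per_patient < 1:
            raise ValueError("need at least one assigned assessment")
        if self.extra_images_mean < 0 or self.duration_noise_sd < 0:
            raise ValueError("rates and noise must be nonnegative")


def generate_cohort(spec: CohortSpec) -> List[AssessmentRecord]:
    """Sample per-image assessment records for both arms.

    Returns records sorted by (group, patient, day, image) with
    deterministic content for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    start = date(2021, 3, 1)
    records: List[AssessmentRecord] = []
    for group, params in (("feedback", spec.feedback), ("basic", spec.basic)):
        for p in range(params.n_patients):
            pid = f"{group[:1].upper()}{p + 1:02d}"
            # per-patient day-skip probability, Beta around the group mean
            kappa = spec.skip_concentration
            mean = min(max(params.skip_prob, 1e-6), 1 - 1e-6)
            p_skip = rng.beta(mean * kappa, (1 - mean) * kappa)
            for day in range(1, spec.assessments_per_patient + 1):
                if rng.random() < p_skip:
                    continue
                n_images = 1 + rng.poisson(spec.extra_images_mean)
                duration = (spec.duration_intercept
                            + spec.duration_slope * day
                            + rng.normal(0.0, spec.duration_noise_sd))
                duration = max(float(duration), 5.0)
                ts = (start + timedelta(days=3 * (day - 1))).isoformat()
                for k in range(n_images):
                    detected = bool(rng.random() < params.detection_prob)
                    ccs = None
                    if detected:
                        ccs = float(rng.lognormal(
                            np.log(params.ccs_median), params.ccs_log_sigma))
                    usable = bool(rng.random() < params.usable_prob)
                    records.append(AssessmentRecord(
                        patient_id=pid,
                        group=group,
                        assessment_index=day,
                        timestamp=ts,
                        checker_detected=detected,
                        usable_label=usable,
                        ccs=ccs,
                        duration_s=duration if k == 0 else None,
                    ))
    return records
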