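"""Color-reference-sticker localization by rectangular morphology.

The sticker is a square 30 x 30 mm marker carrying a 6x6 grid of 36
color patches, placed beside the wound as a color and size reference.
Detection looks for its rectangular morphology and applies a size
threshold:

1. grayscale -> Sobel gradient magnitude -> threshold (Otsu with a
   noise floor) gives an edge map; the patch grid produces a dense edge
   lattice over the sticker,
2. morphological closing bridges small gaps and hole-filling turns the
   lattice into a solid blob,
3. each connected component is fitted with its minimum-area rotated
   rectangle (convex 4-vertex candidate); candidates must fill that
   rectangle well (rectangularity), exceed the configured area fraction
   of the frame, and stay within the aspect-ratio bound for a square
   marker,
4. optionally, the candidate is rectified to a canonical square and the
   spread of 6x6 patch-cell means is checked, which rejects smooth
   blobs (skin, wound) that happen to be rectangle-like.

The largest passing candidate wins; ties break deterministically by
top-left corner position. Failure to find a sticker is a normal
``found=False`` result, never an exception.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon
from skimage import draw, filters, measure, morphology, transform

from .imaging import (
    GrayImage,
    RegionOfInterest,
    SharpnessScore,
    WoundImage,
    to_grayscale,
    variance_of_laplacian,
)

__all__ = [
    "DetectionConfig",
    "CheckerDetection",
    "detect_checker",
    "checker_roi_sharpness",
]

_GRID = 6
_EDGE_FLOOR = 0.02  # Sobel magnitude floor (on [0,1]-scaled gray) below which a scene is featureless
_RECTANGULARITY_MIN = 0.80  # blob area / min-rect area
_RECTIFY_SIZE = 96  # canonical rectified square, pixels
_GRID_MARGIN = 0.08  # fraction trimmed from each side before cell sampling
_EDGE_INSET = 1.5  # px; compensates the outward bias of the thresholded edge band


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds of the sticker detector.

    ``min_area_fraction`` is the size threshold: the candidate's
    rectangle must cover at least this fraction of the frame. The
    default 0.02 leaves a sticker photographed at holder distance
    (roughly 10% of the frame) comfortably above it. ``max_aspect_ratio``
    bounds long/short side for the square marker; ``grid_check`` enables
    patch-structure verification; ``grid_min_std`` is the minimum
    standard deviation of the 36 rectified cell means (gray levels).
    """

    min_area_fraction: float = 0.02
    max_aspect_ratio: float = 1.3
    grid_check: bool = True
    grid_min_std: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_area_fraction < 1.0:
            raise ValueError("min_area_fraction must lie in (0, 1)")
        if self.max_aspect_ratio < 1.0:
            raise ValueError("max_aspect_ratio must be >= 1")
        if self.grid_min_std < 0:
            raise ValueError("grid_min_std must be nonnegative")


@dataclass(frozen=True)
class CheckerDetection:
    """Outcome of sticker localization.

    When ``found`` is true, ``corners`` holds the 4 rectangle corners
    ordered clockwise from the top-left (pixel coordinates, origin at
    the image's top-left, 0-based), ``area_fraction`` the rectangle area
    over the image area, and ``roi`` the filled-quadrilateral mask.
    ``too_small_candidate`` records whether some convex 4-vertex
    candidate failed *only* the size threshold, which the quality gate
    uses to tell "sticker too small" from "no sticker".
    """

    found: bool
    corners: Optional[np.ndarray] = None
    area_fraction: Optional[float] = None
    roi: Optional[RegionOfInterest] = None
    too_small_candidate: bool = False

    def __post_init__(self) -> None:
        if self.found and (self.corners is None or self.area_fraction is None
                           or self.roi is None):
            raise ValueError("found=True requires corners, area_fraction and roi")


def _order_corners(pts: np.ndarray) -> np.ndarray:
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    pts = pts[np.argsort(ang)]  # clockwise with y pointing down
    start = int(np.argmin(pts.sum(axis=1)))
    return np.roll(pts, -start, axis=0)


def _min_area_rect(region_mask: np.ndarray, offset: Tuple[int, int]) -> Optional[np.ndarray]:
    """Minimum rotated rectangle of a component, as (4,2) xy corners."""
    rr, cc = np.nonzero(region_mask)
    if rr.size < 4:
        return None
    # pixel extents, not centers, so the rectangle hugs the blob outline
    y0, x0 = offset
    pts = np.column_stack([cc + x0, rr + y0]).astype(float)
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon):
        return None
    rect = hull.minimum_rotated_rectangle
    if not isinstance(rect, Polygon):
        return None
    corners = _order_corners(np.asarray(rect.exterior.coords[:4], dtype=float))
    return _inset_rect(corners, _EDGE_INSET)


def _inset_rect(corners: np.ndarray, delta: float) -> np.ndarray:
    """Shrink a rectangle by ``delta`` pixels on every side.

    The thresholded Sobel edge band straddles the true sticker boundary,
    so the blob (and its minimum rectangle) overshoots outward by about
    the band's half-width; the inset pulls the corners — and with them
    the sharpness ROI — back onto the sticker.
    """
    center = corners.mean(axis=0)
    u = corners[1] - corners[0]
    v = corners[3] - corners[0]
    lu, lv = np.linalg.norm(u), np.linalg.norm(v)
    if lu <= 2 * delta or lv <= 2 * delta:
        return corners
    u, v = u / lu, v / lv
    half_u, half_v = lu / 2 - delta, lv / 2 - delta
    signs = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    return center + np.outer(signs[:, 0], half_u * u) + np.outer(signs[:, 1], half_v * v)


def _grid_structure_ok(gray: GrayImage, corners: np.ndarray,
                       config: DetectionConfig) -> bool:
    """Check the 6x6 patch structure inside a rectified candidate."""
    size = _RECTIFY_SIZE
    dst = np.array([[0, 0], [size - 1, 0], [size - 1, size - 1], [0, size - 1]],
                   dtype=float)
    tf = transform.ProjectiveTransform.from_estimate(dst, corners)
    if not tf:
        return False
    rectified = transform.warp(gray.pixels, tf, output_shape=(size, size),
                               order=1, mode="edge", preserve_range=True)
    m = int(round(_GRID_MARGIN * size))
    inner = rectified[m:size - m, m:size - m]
    cell = inner.shape[0] / _GRID
    means = np.empty(_GRID * _GRID)
    for i in range(_GRID):
        for j in range(_GRID):
            r0, r1 = int(i * cell), int((i + 1) * cell)
            c0, c1 = int(j * cell), int((j + 1) * cell)
            # sample the central half of the cell to tolerate misalignment
            pr, pc = (r1 - r0) // 4, (c1 - c0) // 4
            means[i * _GRID + j] = inner[r0 + pr:r1 - pr, c0 + pc:c1 - pc].mean()
    return float(np.std(means)) >= config.grid_min_std


def _quad_roi(corners: np.ndarray, shape: Tuple[int, int]) -> RegionOfInterest:
    rr, cc = draw.polygon(corners[:, 1], corners[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return RegionOfInterest(mask)


def detect_checker(image: WoundImage,
                   config: DetectionConfig = DetectionConfig()) -> CheckerDetection:
    """Locate the color reference sticker in a wound photograph.

    Returns a ``found=False`` detection when no candidate passes the
    morphology, size and structure checks; identical image and config
    always give the identical result.
    """
    gray = to_grayscale(image)
    h, w = gray.pixels.shape

    edges = filters.sobel(gray.pixels / 255.0)
    if edges.max() < _EDGE_FLOOR:
        return CheckerDetection(found=False)
    thr = max(filters.threshold_otsu(edges), _EDGE_FLOOR)
    edge_map = edges > thr

    # Defocus widens the gaps in the patch-grid edge lattice, so the
    # closing radius is escalated until some candidate survives; sharp
    # scenes resolve at the smallest radius, where corners are tightest.
    too_small = False
    for radius in (2, 4, 6):
        closed = morphology.closing(edge_map, morphology.disk(radius))
        solid = ndimage.binary_fill_holes(closed)
        detection = _best_candidate(gray, solid, config)
        too_small = too_small or detection.too_small_candidate
        if detection.found:
            return dataclasses.replace(detection, too_small_candidate=too_small)
    return CheckerDetection(found=False, too_small_candidate=too_small)


def _best_candidate(gray: GrayImage, solid: np.ndarray,
                    config: DetectionConfig) -> CheckerDetection:
    """Fit and filter rectangle candidates in a solidified edge mask."""
    h, w = solid.shape
    image_area = float(h * w)
    labels = measure.label(solid, connectivity=2)

    min_rect_area = config.min_area_fraction * image_area
    passing: List[Tuple[float, float, float, np.ndarray]] = []
    too_small = False
    for region in measure.regionprops(labels):
        if region.area < 0.5 * min_rect_area:
            # too small even before the rectangle fit; skip cheaply, but a
            # moderately undersized rectangle-like blob should still count
            # toward the "too small" diagnosis
            if region.area < 0.05 * min_rect_area:
                continue
        y0, x0, y1, x1 = region.bbox
        corners = _min_area_rect(region.image, (y0, x0))
        if corners is None:
            continue
        sides = np.linalg.norm(np.roll(corners, -1, axis=0) - corners, axis=1)
        short, long_ = float(sides.min()), float(sides.max())
        if short <= 0:
            continue
        rect_area = float(Polygon(corners).area)
        if rect_area <= 0:
            continue
        if region.area / rect_area < _RECTANGULARITY_MIN:
            continue
        if long_ / short > config.max_aspect_ratio:
            continue
        if config.grid_check and not _grid_structure_ok(gray, corners, config):
            continue
        if rect_area < min_rect_area:
            too_small = True  # passed every morphology check except size
            continue
        passing.append((rect_area, corners[0, 1], corners[0, 0], corners))

    if not passing:
        return CheckerDetection(found=False, too_small_candidate=too_small)
    # largest area wins; deterministic tie-break by top-left corner (y, x)
    passing.sort(key=lambda t: (-t[0], t[1], t[2]))
    rect_area, _, _, corners = passing[0]
    return CheckerDetection(
        found=True,
        corners=corners,
        area_fraction=rect_area / image_area,
        roi=_quad_roi(corners, (h, w)),
        too_small_candidate=too_small,
    )


def checker_roi_sharpness(image: WoundImage,
                          detection: CheckerDetection) -> SharpnessScore:
    """Color checker sharpness: variance of the Laplacian over the sticker ROI.

    Raises
    ------
    ValueError
        If the detection did not find a sticker.
    """
    if not detection.found or detection.roi is None:
        raise ValueError("no checker detected; CCS is undefined")
    return variance_of_laplacian(to_grayscale(image), detection.roi)
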