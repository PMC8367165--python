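"""Pixel-level primitives for wound-image sharpness scoring.

Sharpness is measured as the variance of the Laplacian response: the
Laplacian is a discrete second-derivative operator that responds to rapid
intensity changes (edges, texture), and its variance over an image region
grows with the amount of fine detail in focus. Defocus blur attenuates
high spatial frequencies, so blurrier images score lower.

All scores here are computed at native resolution on a luma (grayscale)
conversion of the RGB input; both conventions are documented contracts of
this package (see the methods note), since focus measures are resolution-
and channel-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "WoundImage",
    "GrayImage",
    "RegionOfInterest",
    "SharpnessScore",
    "to_grayscale",
    "laplacian",
    "variance_of_laplacian",
]

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: 4-connected discrete Laplacian stencil.
LAPLACIAN_KERNEL = np.array(
    [[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]]
)


@dataclass
class WoundImage:
    """An 8-bit RGB wound photograph with optional acquisition metadata.

    Parameters
    ----------
    pixels : ndarray of shape (height, width, 3), dtype uint8
        RGB raster, channel values in [0, 255].
    patient_id, wound_location, timestamp : str, optional
        Acquisition metadata carried through the pipeline untouched.
    """

    pixels: np.ndarray
    patient_id: Optional[str] = None
    wound_location: Optional[str] = None
    timestamp: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"expected (H, W, 3) RGB pixel array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.dtype != np.uint8:
            if np.nanmin(px) < 0 or np.nanmax(px) > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class GrayImage:
    """A real-valued single-channel image with intensities in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected 2D intensity array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class RegionOfInterest:
    """Boolean pixel mask restricting a computation to an image subregion."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError(f"ROI mask must be 2D, got shape {m.shape}")
        self.mask = m.astype(bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SharpnessScore:
    """Variance-of-Laplacian focus score (intensity² units).

    Attributes
    ----------
    value : float
        Population variance of the Laplacian response over the scored
        pixels; nonnegative, zero iff the response is constant there.
    n_pixels : int
        Number of pixels that entered the variance.
    """

    value: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("sharpness score cannot be negative")
        if self.n_pixels < 1:
            raise ValueError("score must cover at least one pixel")


def to_grayscale(image: WoundImage) -> GrayImage:
    """Convert an RGB image to BT.601 luma (0.299 R + 0.587 G + 0.114 B)."""
    rgb = image.pixels.astype(np.float64)
    wr, wg, wb = LUMA_WEIGHTS
    return GrayImage(wr * rgb[..., 0] + wg * rgb[..., 1] + wb * rgb[..., 2])


def laplacian(gray: GrayImage) -> GrayImage:
    """Discrete Laplacian response with the 4-connected 3x3 stencil.

    Border pixels use replicate (edge-clamp) padding. The response is a
    signed real grid of the same shape as the input.

    Raises
    ------
    ValueError
        If the image is smaller than the 3x3 kernel.
    """
    if gray.height < 3 or gray.width < 3:
        raise ValueError(
            f"image {gray.height}x{gray.width} is smaller than the 3x3 kernel"
        )
    out = ndimage.convolve(gray.pixels, LAPLACIAN_KERNEL, mode="nearest")
    resp = GrayImage.__new__(GrayImage)
    resp.pixels = out  # bypass validation: response is signed by design
    return resp


def variance_of_laplacian(
    gray: GrayImage, roi: Optional[RegionOfInterest] = None
) -> SharpnessScore:
    """Population variance of the Laplacian response, optionally over an ROI.

    Parameters
    ----------
    gray : GrayImage
        Intensity image, at least 3x3.
    roi : RegionOfInterest, optional
        Mask aligned with `gray`; must select at least 2 pixels. When
        omitted the whole image is scored.

    Returns
    -------
    SharpnessScore
        Variance (divide-by-N) of the response over the selected pixels.
    """
    resp = laplacian(gray).pixels
    if roi is None:
        values = resp.ravel()
    else:
        if roi.mask.shape != resp.shape:
            raise ValueError(
                f"ROI shape {roi.mask.shape} does not match image {resp.shape}"
            )
        values = resp[roi.mask]
        if values.size < 2:
            raise ValueError("ROI selects fewer than 2 pixels")
    return SharpnessScore(value=float(np.var(values)), n_pixels=int(values.size))
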