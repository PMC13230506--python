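"""Refinement of coarse ROI masks into clean measurement regions.

Two modality-specific routes:

* fingernail — iterative single-pixel boundary erosion of the coarse mask
  (4-connected structuring element), keeping the snapshot whose retained
  pixel fraction is closest to a 30% target;
* eyelid — gradient-magnitude edge detection (Otsu threshold) plus a Hough
  circle vote, taking the lower segment of the best circle; falls back to
  the eroded coarse mask when no circle scores above the vote minimum.

Whether the 30% retention in the source procedure was a fixed iteration
count or an adaptive stop is unknown; the adaptive closest-snapshot rule
here is a documented implementation decision.

Coordinates are 0-based row-major (row, col).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.filters import sobel, threshold_otsu
from skimage.transform import hough_circle

__all__ = [
    "BinaryMask",
    "CircleFit",
    "ArcDetectionError",
    "EmptyMaskError",
    "erode_mask",
    "detect_eyelid_arc",
    "lower_segment_mask",
    "refine_fingernail",
    "refine_eyelid",
]

# 4-connected (cross) structuring element
_CROSS = ndimage.generate_binary_structure(2, 1)

#: masks smaller than this are returned unchanged, flagged degenerate
MIN_MASK_PIXELS = 25


class ArcDetectionError(RuntimeError):
    """No accumulator cell reached the minimum vote count."""


class EmptyMaskError(ValueError):
    """A geometric mask has no pixel inside the image bounds."""


@dataclass
class BinaryMask:
    """Boolean pixel mask plus its retained fraction w.r.t. a reference mask."""

    pixels: np.ndarray
    retained_fraction: float = 1.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class CircleFit:
    """A circle in (row, col) pixel coordinates with its accumulator score."""

    center: tuple[float, float]  # (row, col)
    radius: float
    accumulator_score: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.accumulator_score < 0:
            raise ValueError("accumulator score must be non-negative")


def _mask_array(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.pixels
    return np.asarray(mask, dtype=bool)


def erode_mask(
    mask,
    target_fraction: float = 0.30,
    min_pixels: int = MIN_MASK_PIXELS,
) -> BinaryMask:
    """Iteratively erode a mask toward a target retained fraction.

    Single-pixel boundary erosions (4-connected) are applied repeatedly;
    among the snapshots {original, after 1 erosion, ...} the one whose
    retained fraction is closest to ``target_fraction`` is returned (ties
    resolve to fewer erosions).  The result is always a subset of the input.

    Masks with fewer than ``min_pixels`` foreground pixels are returned
    unchanged with ``degenerate=True``.
    """
    pixels = _mask_array(mask)
    if not (0.0 < target_fraction <= 1.0):
        raise ValueError("target_fraction must lie in (0, 1]")
    reference = int(pixels.sum())
    if reference == 0:
        raise ValueError("cannot erode an empty mask")
    if reference < min_pixels:
        return BinaryMask(pixels.copy(), retained_fraction=1.0, degenerate=True)

    best = pixels.copy()
    best_fraction = 1.0
    best_diff = abs(1.0 - target_fraction)
    current = pixels
    while True:
        current = ndimage.binary_erosion(current, structure=_CROSS, border_value=0)
        count = int(current.sum())
        if count == 0:
            break
        fraction = count / reference
        diff = abs(fraction - target_fraction)
        if diff < best_diff:
            best = current.copy()
            best_fraction = fraction
            best_diff = diff
        if fraction <= target_fraction:
            break
    return BinaryMask(best, retained_fraction=best_fraction)


def detect_eyelid_arc(
    image: np.ndarray,
    radius_fractions: tuple[float, float] = (0.2, 0.6),
    min_score: float = 0.25,
    radius_bounds: Optional[tuple[int, int]] = None,
) -> CircleFit:
    """Find the best-fitting circle in an eyelid patch.

    The edge map is the Sobel gradient magnitude thresholded at the Otsu
    level.  A Hough accumulator votes over a discretized (center, radius)
    grid with 1-px radius steps spanning ``radius_fractions`` of the smaller
    image dimension; votes are normalized by circumference.  The
    maximum-score circle wins; equal votes resolve to the larger radius.
    ``radius_bounds`` (px) overrides the fraction-based grid, e.g. when the
    patch is a tight crop around a half-circular region.

    Raises
    ------
    ArcDetectionError
        If the image has no edges or no accumulator cell reaches
        ``min_score`` (callers may fall back to the coarse mask).
    """
    arr = np.asarray(image)
    gray = rgb2gray(arr) if arr.ndim == 3 else arr.astype(float)
    grad = sobel(gray)
    if float(np.ptp(grad)) == 0.0:
        raise ArcDetectionError("uniform image: no edges")
    edges = grad > threshold_otsu(grad)
    if not edges.any():
        raise ArcDetectionError("no edge pixels above threshold")

    if radius_bounds is not None:
        r_lo, r_hi = radius_bounds
        r_lo = max(3, int(r_lo))
        r_hi = max(r_lo, int(r_hi))
    else:
        m = min(gray.shape)
        r_lo = max(3, int(round(radius_fractions[0] * m)))
        r_hi = max(r_lo, int(round(radius_fractions[1] * m)))
    radii = np.arange(r_lo, r_hi + 1)
    acc = hough_circle(edges, radii, normalize=True)
    max_score = float(acc.max())
    if max_score < min_score:
        raise ArcDetectionError(
            f"best accumulator score {max_score:.3f} below minimum {min_score}"
        )
    # tie-break: larger radius first, then smaller (row, col) for determinism
    hits = np.argwhere(acc == max_score)
    ri, row, col = max(hits.tolist(), key=lambda h: (h[0], -h[1], -h[2]))
    return CircleFit(
        center=(float(row), float(col)),
        radius=float(radii[ri]),
        accumulator_score=max_score,
    )


def lower_segment_mask(circle: CircleFit, image_shape: tuple[int, int]) -> BinaryMask:
    """Mask of the lower segment of a circle, clipped to the image bounds.

    A pixel belongs to the segment when it lies strictly inside the circle
    (distance < radius) and its row coordinate is >= the center row.

    Raises
    ------
    EmptyMaskError
        If the segment contains no pixel inside the image.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    rows, cols = np.ogrid[:h, :w]
    cr, cc = circle.center
    inside = (rows - cr) ** 2 + (cols - cc) ** 2 < circle.radius**2
    segment = inside & (rows >= cr)
    if not segment.any():
        raise EmptyMaskError("lower circle segment lies entirely outside the image")
    return BinaryMask(segment)


def refine_fingernail(coarse_mask, target_fraction: float = 0.30) -> BinaryMask:
    """Fingernail route: erosion of the coarse mask only."""
    return erode_mask(coarse_mask, target_fraction=target_fraction)


def refine_eyelid(
    image: np.ndarray,
    coarse_mask,
    target_fraction: float = 0.30,
    pad: int = 4,
    min_score: float = 0.25,
) -> tuple[BinaryMask, dict]:
    """Eyelid route: crop to the coarse mask, detect the circular arc, keep
    the lower segment intersected with the coarse mask.

    On detection failure the eroded coarse mask is returned instead.  The
    info dict records the fallback flag and, on success, the circle
    parameters in full-image coordinates.
    """
    coarse = _mask_array(coarse_mask)
    if not coarse.any():
        raise ValueError("coarse mask is empty")
    rows = np.flatnonzero(coarse.any(axis=1))
    cols = np.flatnonzero(coarse.any(axis=0))
    r0 = max(0, rows[0] - pad)
    r1 = min(coarse.shape[0], rows[-1] + 1 + pad)
    c0 = max(0, cols[0] - pad)
    c1 = min(coarse.shape[1], cols[-1] + 1 + pad)
    patch = np.asarray(image)[r0:r1, c0:c1]
    # the crop of a lower circle segment spans ~2r x r, so size the radius
    # grid from the larger crop dimension rather than the smaller one
    long_side = max(patch.shape[0], patch.shape[1])
    bounds = (int(0.2 * long_side), int(0.8 * long_side))
    try:
        local = detect_eyelid_arc(patch, min_score=min_score, radius_bounds=bounds)
    except ArcDetectionError as exc:
        refined = erode_mask(coarse, target_fraction=target_fraction)
        return refined, {"fallback": True, "reason": str(exc)}
    circle = CircleFit(
        center=(local.center[0] + r0, local.center[1] + c0),
        radius=local.radius,
        accumulator_score=local.accumulator_score,
    )
    try:
        segment = lower_segment_mask(circle, coarse.shape)
    except EmptyMaskError as exc:
        refined = erode_mask(coarse, target_fraction=target_fraction)
        return refined, {"fallback": True, "reason": str(exc)}
    refined_pixels = segment.pixels & coarse
    if not refined_pixels.any():
        refined = erode_mask(coarse, target_fraction=target_fraction)
        return refined, {"fallback": True, "reason": "segment misses coarse mask"}
    fraction = float(refined_pixels.sum() / coarse.sum())
    info = {
        "fallback": False,
        "circle": {
            "center_row": circle.center[0],
            "center_col": circle.center[1],
            "radius": circle.radius,
            "accumulator_score": circle.accumulator_score,
        },
    }
    return BinaryMask(refined_pixels, retained_fraction=fraction), info
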