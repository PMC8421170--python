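"""Foreground-mask cleanup and moment-based sperm-head detection.

The raw foreground mask still carries speckle from sensor noise and ragged
object outlines. Morphological opening removes structures smaller than the
structuring element and closing fills holes; a disk element preserves the
rounded head outline better than line or square elements.

Candidate heads are then the 8-connected components of the cleaned mask.
Their centroids come from the zero- and first-order moments of the binary
region (n00 = pixel count, n10 = sum of x, n01 = sum of y), and an ellipse
with matching second central moments supplies the semi-axes used by the
elliptical-area filter: regions whose elliptical area pi*a*b falls below
``min_area`` (default 150 px^2) are debris and are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk, opening

__all__ = [
    "MorphologyParams",
    "Region",
    "SpermDetection",
    "DEFAULT_MIN_AREA",
    "clean_mask",
    "label_regions",
    "ellipse_area",
    "filter_detections",
    "detect_in_mask",
]

#: Minimum elliptical area (px^2) for a region to count as a sperm head.
DEFAULT_MIN_AREA = 150.0

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


def _line_footprint(radius: int) -> np.ndarray:
    fp = np.zeros((1, 2 * radius + 1), dtype=bool)
    fp[:] = True
    return fp


@dataclass(frozen=True)
class MorphologyParams:
    """Structuring element used by :func:`clean_mask`."""

    se_shape: str = "disk"  # disk | square | line
    se_radius: int = 3

    def __post_init__(self) -> None:
        if self.se_radius < 1:
            raise ValueError("se_radius must be >= 1")
        if self.se_shape not in ("disk", "square", "line"):
            raise ValueError(f"unknown structuring element {self.se_shape!r}")

    def footprint(self) -> np.ndarray:
        if self.se_shape == "disk":
            return disk(self.se_radius)
        if self.se_shape == "square":
            side = 2 * self.se_radius + 1
            return np.ones((side, side), dtype=bool)
        return _line_footprint(self.se_radius)


@dataclass(frozen=True)
class Region:
    """One connected foreground component with its moment summary.

    ``centroid`` is ``(x_c, y_c) = (n10/n00, n01/n00)``; ``semi_major`` and
    ``semi_minor`` are the semi-axes of the ellipse whose second central
    moments match the region's.
    """

    pixel_count: int  # n00
    sum_x: float  # n10
    sum_y: float  # n01
    centroid: tuple[float, float]
    semi_major: float
    semi_minor: float
    elliptical_area: float


@dataclass(frozen=True)
class SpermDetection:
    """A candidate sperm head in one frame."""

    frame_index: int
    centroid: tuple[float, float]
    elliptical_area: float
    pixel_area: float


def clean_mask(mask: np.ndarray, params: MorphologyParams | None = None) -> np.ndarray:
    """Morphological opening followed by closing with the same element."""
    if params is None:
        params = MorphologyParams()
    binary = np.asarray(mask).astype(bool)
    fp = params.footprint()
    cleaned = closing(opening(binary, fp), fp)
    return cleaned.astype(np.uint8)


def _moment_ellipse(ys: np.ndarray, xs: np.ndarray) -> tuple[float, float]:
    """Semi-axes of the constant-density ellipse matching the region's
    second central moments.

    For a solid ellipse with semi-axes (a, b) the central second moment
    along the major axis is a^2/4, so a = 2*sqrt(lambda_max) with lambda
    the eigenvalues of the 2x2 covariance of the pixel coordinates
    (pixel-centre point cloud, the standard blob-analysis convention).
    """
    x0, y0 = xs.mean(), ys.mean()
    dx, dy = xs - x0, ys - y0
    mxx = (dx * dx).mean()
    myy = (dy * dy).mean()
    mxy = (dx * dy).mean()
    common = math.hypot(mxx - myy, 2.0 * mxy) / 2.0
    half_sum = (mxx + myy) / 2.0
    l1 = max(half_sum + common, 1e-12)
    l2 = max(half_sum - common, 1e-12)
    return 2.0 * math.sqrt(l1), 2.0 * math.sqrt(l2)


def label_regions(mask: np.ndarray) -> list[Region]:
    """8-connected components of a binary mask with moment summaries."""
    binary = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(binary, structure=_EIGHT_CONNECTED)
    regions: list[Region] = []
    for ys, xs in ndimage.value_indices(labels, ignore_value=0).values():
        n00 = int(ys.size)
        n10 = float(xs.sum())
        n01 = float(ys.sum())
        a, b = _moment_ellipse(ys.astype(float), xs.astype(float))
        regions.append(
            Region(
                pixel_count=n00,
                sum_x=n10,
                sum_y=n01,
                centroid=(n10 / n00, n01 / n00),
                semi_major=a,
                semi_minor=b,
                elliptical_area=ellipse_area(a, b),
            )
        )
    return regions


def ellipse_area(a: float, b: float) -> float:
    """Area pi*a*b of an ellipse given its SEMI-axes."""
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    return math.pi * a * b


def filter_detections(
    regions: list[Region],
    min_area: float = DEFAULT_MIN_AREA,
    frame_index: int = 0,
    axis_convention: str = "semi",
) -> list[SpermDetection]:
    """Keep regions whose elliptical area reaches ``min_area``.

    ``axis_convention="full"`` evaluates the filter with full axes
    (quadrupling the elliptical area); the default semi-axis form is the
    standard ellipse-area formula. Survivors are ordered by centroid
    (y, x) so downstream processing is deterministic.
    """
    if axis_convention not in ("semi", "full"):
        raise ValueError(f"unknown axis convention {axis_convention!r}")
    factor = 4.0 if axis_convention == "full" else 1.0
    kept = [r for r in regions if factor * r.elliptical_area >= min_area]
    kept.sort(key=lambda r: (r.centroid[1], r.centroid[0]))
    return [
        SpermDetection(
            frame_index=frame_index,
            centroid=r.centroid,
            elliptical_area=factor * r.elliptical_area,
            pixel_area=float(r.pixel_count),
        )
        for r in kept
    ]


def detect_in_mask(
    mask: np.ndarray,
    frame_index: int,
    morph_params: MorphologyParams | None = None,
    min_area: float = DEFAULT_MIN_AREA,
) -> list[SpermDetection]:
    """Convenience pipeline: clean, label and filter one foreground mask."""
    return filter_detections(
        label_regions(clean_mask(mask, morph_params)), min_area, frame_index
    )
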