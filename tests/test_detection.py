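"""Morphological cleanup, moment centroids and the elliptical-area filter."""

import math

import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.measure import label as sk_label, regionprops

from spermtrack import (
    MorphologyParams,
    clean_mask,
    ellipse_area,
    filter_detections,
    label_regions,
)
from spermtrack.detection import Region


def _random_mask(rng, shape=(40, 40), p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)


def _random_blob(rng, shape=(64, 64), n_seeds=4, iterations=6):
    """A connected random blob grown by dilation from seed points."""
    mask = np.zeros(shape, bool)
    r0 = rng.integers(20, 44)
    c0 = rng.integers(20, 44)
    mask[r0, c0] = True
    grow = rng.random((iterations,) + shape) < 0.7
    for g in grow:
        mask |= ndimage.binary_dilation(mask) & g
    mask = ndimage.binary_dilation(mask)  # guarantee > 1 px
    return mask.astype(np.uint8)


def test_opening_removes_single_speck():
    mask = np.zeros((20, 20), np.uint8)
    mask[10, 10] = 1
    assert clean_mask(mask, MorphologyParams("disk", 3)).sum() == 0


def test_smooth_shape_survives_almost_unchanged():
    """Opening/closing are identity on shapes everywhere containing the
    SE: exactly so for a rectangle with a square SE, and up to boundary
    rasterization for a large disk with a disk SE."""
    rect = np.zeros((40, 40), np.uint8)
    rect[10:30, 8:28] = 1
    assert (clean_mask(rect, MorphologyParams("square", 3)) == rect).all()

    mask = np.zeros((40, 40), np.uint8)
    rr, cc = draw_disk((20, 20), 10)
    mask[rr, cc] = 1
    cleaned = clean_mask(mask, MorphologyParams("disk", 3)).astype(bool)
    inner = np.zeros_like(mask, bool)
    rr, cc = draw_disk((20, 20), 8)
    inner[rr, cc] = True
    outer = np.zeros_like(mask, bool)
    rr, cc = draw_disk((20, 20), 12)
    outer[rr, cc] = True
    assert (cleaned >= inner).all()  # interior intact
    assert (cleaned <= outer).all()  # no growth beyond the rim


def test_closing_fills_interior_hole():
    mask = np.zeros((40, 40), np.uint8)
    rr, cc = draw_disk((20, 20), 8)
    mask[rr, cc] = 1
    mask[20, 20] = 0
    cleaned = clean_mask(mask, MorphologyParams("disk", 2))
    assert cleaned[20, 20] == 1


def test_clean_mask_matches_erosion_dilation_composition(rng):
    """Opening-then-closing must equal the independent scipy composition
    erode-dilate-dilate-erode with the same structuring element."""
    fp = MorphologyParams("disk", 2).footprint()
    for _ in range(50):
        mask = _random_mask(rng)
        ours = clean_mask(mask, MorphologyParams("disk", 2)).astype(bool)
        opened = ndimage.binary_dilation(
            ndimage.binary_erosion(mask, structure=fp), structure=fp
        )
        closed = ndimage.binary_erosion(
            ndimage.binary_dilation(opened, structure=fp), structure=fp
        )
        assert (ours == closed).all()


def test_opening_and_closing_bracket_the_input(rng):
    fp = MorphologyParams("disk", 2).footprint()
    for _ in range(20):
        mask = _random_mask(rng).astype(bool)
        mask[:3] = mask[-3:] = mask[:, :3] = mask[:, -3:] = False  # off-border
        opened = ndimage.binary_dilation(ndimage.binary_erosion(mask, fp), fp)
        closed = ndimage.binary_erosion(ndimage.binary_dilation(mask, fp), fp)
        assert (opened <= mask).all()
        assert (mask <= closed).all()


def test_single_pixel_region():
    mask = np.zeros((10, 10), np.uint8)
    mask[4, 7] = 1  # row 4, column 7
    (region,) = label_regions(mask)
    assert region.pixel_count == 1
    assert region.centroid == (7.0, 4.0)


def test_square_block_centroid():
    mask = np.zeros((10, 10), np.uint8)
    mask[0:2, 0:2] = 1
    (region,) = label_regions(mask)
    assert region.pixel_count == 4
    assert region.centroid == (0.5, 0.5)


def test_centroid_equals_brute_force_mean(rng):
    """Moment centroids must equal explicit per-pixel coordinate means."""
    for _ in range(100):
        blob = _random_blob(rng)
        (region,) = label_regions(blob)
        sx = sy = n = 0.0
        for r in range(blob.shape[0]):
            for c in range(blob.shape[1]):
                if blob[r, c]:
                    sx += c
                    sy += r
                    n += 1
        assert region.pixel_count == n
        assert region.centroid[0] == pytest.approx(sx / n, abs=1e-9)
        assert region.centroid[1] == pytest.approx(sy / n, abs=1e-9)


def test_moment_ellipse_matches_regionprops(rng):
    """Semi-axes must agree with the independent scikit-image moment
    ellipse (regionprops axis lengths are full axes)."""
    for _ in range(20):
        blob = _random_blob(rng)
        (region,) = label_regions(blob)
        props = regionprops(sk_label(blob, connectivity=2))[0]
        assert region.semi_major == pytest.approx(props.axis_major_length / 2, rel=1e-6, abs=1e-6)
        assert region.semi_minor == pytest.approx(props.axis_minor_length / 2, rel=1e-6, abs=1e-6)


def test_eight_connectivity_links_diagonals():
    mask = np.eye(5, dtype=np.uint8)
    assert len(label_regions(mask)) == 1


def test_empty_mask_yields_no_regions():
    assert label_regions(np.zeros((5, 5), np.uint8)) == []


def test_ellipse_area_closed_forms():
    assert ellipse_area(3.0, 3.0) == pytest.approx(math.pi * 9)
    assert ellipse_area(5.0, 3.0) == pytest.approx(15 * math.pi)
    assert ellipse_area(10.0, 5.0) == pytest.approx(157.0796, abs=1e-3)
    with pytest.raises(ValueError):
        ellipse_area(0.0, 3.0)


def _region(area, x=0.0, y=0.0):
    a = math.sqrt(area / math.pi)
    return Region(
        pixel_count=int(area), sum_x=x, sum_y=y, centroid=(x, y),
        semi_major=a, semi_minor=a, elliptical_area=area,
    )


def test_area_filter_boundary_is_inclusive():
    kept = filter_detections([_region(149.9), _region(150.0)], min_area=150.0)
    assert [d.elliptical_area for d in kept] == [150.0]


def test_area_filter_orders_by_centroid():
    regions = [_region(200, x=5, y=9), _region(200, x=1, y=2), _region(200, x=0, y=2)]
    kept = filter_detections(regions)
    assert [d.centroid for d in kept] == [(0, 2), (1, 2), (5, 9)]


def test_full_axis_convention_quadruples_area():
    (d,) = filter_detections([_region(40.0)], min_area=150.0, axis_convention="full")
    assert d.elliptical_area == pytest.approx(160.0)
    assert filter_detections([_region(40.0)], min_area=150.0) == []


def test_empty_region_list():
    assert filter_detections([], 150.0) == []
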