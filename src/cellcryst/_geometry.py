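"""Polygon/mask geometry helpers shared across the package.

Coordinate convention (package-wide): 0-based, (x, y) = (column, row),
origin at the top-left corner, pixel (r, c) occupying the unit square
[c, c+1) x [r, r+1) with its center at (c + 0.5, r + 0.5).
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import measure

__all__ = [
    "rasterize_polygon",
    "polygon_area",
    "trace_mask_to_polygon",
    "tight_bbox",
    "mask_centroid",
]


def rasterize_polygon(polygon: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean mask.

    A pixel is foreground iff its center lies strictly inside the polygon
    under the even-odd (crossing-number) rule.  Vertices are (x, y) floats;
    the polygon is closed implicitly.  Degenerate (zero-area) polygons yield
    an all-background mask and a warning.

    Parameters
    ----------
    polygon
        (n, 2) array of (x, y) vertices, n >= 3.
    image_shape
        (height, width) of the target mask.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("polygon must be an (n, 2) array with n >= 3")
    h, w = image_shape
    mask = np.zeros((h, w), dtype=bool)
    # degenerate = all vertices collinear (bow-ties have zero shoelace area
    # but a nonzero even-odd interior, so the shoelace sum is not the test)
    rel = poly[1:] - poly[0]
    if np.abs(rel[:-1, 0] * rel[1:, 1] - rel[:-1, 1] * rel[1:, 0]).max(initial=0.0) < 1e-9:
        warnings.warn("degenerate (zero-area) polygon rasterized to empty mask",
                      stacklevel=2)
        return mask

    x1 = poly[:, 0]
    y1 = poly[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    # rows whose center yc = r + 0.5 can be covered
    r_lo = max(0, int(np.floor(poly[:, 1].min() - 0.5)))
    r_hi = min(h - 1, int(np.ceil(poly[:, 1].max())))
    nonhorz = y1 != y2
    ex1, ey1 = x1[nonhorz], y1[nonhorz]
    ex2, ey2 = x2[nonhorz], y2[nonhorz]
    if ex1.size == 0:
        return mask
    for r in range(r_lo, r_hi + 1):
        yc = r + 0.5
        # half-open rule [min(y), max(y)) avoids double-counting shared vertices
        hit = (np.minimum(ey1, ey2) <= yc) & (yc < np.maximum(ey1, ey2))
        if not hit.any():
            continue
        xs = ex1[hit] + (yc - ey1[hit]) * (ex2[hit] - ex1[hit]) / (ey2[hit] - ey1[hit])
        xs = np.sort(xs)
        # even-odd: a center is inside iff an odd number of crossings lie
        # strictly to its right, i.e. in the half-open spans [xs_i, xs_{i+1})
        for i in range(0, xs.size - 1, 2):
            c_lo = int(np.ceil(xs[i] - 0.5))
            c_hi = int(np.ceil(xs[i + 1] - 0.5)) - 1
            if c_hi < 0 or c_lo > w - 1:
                continue
            mask[r, max(c_lo, 0):min(c_hi, w - 1) + 1] = True
    return mask


def polygon_area(polygon: np.ndarray) -> float:
    """Signed shoelace area of an (n, 2) (x, y) polygon."""
    p = np.asarray(polygon, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def trace_mask_to_polygon(mask: np.ndarray) -> np.ndarray:
    """Trace the outline of a binary mask as an (n, 2) (x, y) polygon.

    Uses the longest 0.5-level contour of the padded mask.  The result is
    approximate (sub-pixel contour through pixel-edge midpoints); it is meant
    for exporting mask-only instances to polygon annotation formats, not for
    exact round-tripping.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("cannot trace an empty mask to a polygon")
    padded = np.pad(m.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    # (row, col) in padded frame -> (x, y) in image frame; pad offset is 1,
    # and find_contours coordinates index pixel centers, hence +0.5 - 1.
    xy = np.stack([contour[:, 1] - 0.5, contour[:, 0] - 0.5], axis=1)
    # light decimation: drop collinear runs
    if len(xy) > 3:
        keep = np.ones(len(xy), dtype=bool)
        v1 = xy[1:-1] - xy[:-2]
        v2 = xy[2:] - xy[1:-1]
        cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
        keep[1:-1] = np.abs(cross) > 1e-9
        xy = xy[keep]
    return xy


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight bounding box (x_min, y_min, x_max, y_max), max edges inclusive."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask has no bounding box")
    return int(cols[0]), int(rows[0]), int(cols[-1]), int(rows[-1])


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Foreground centroid as (x, y) in pixel-center coordinates."""
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("empty mask has no centroid")
    return float(cc.mean() + 0.5), float(rr.mean() + 0.5)
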