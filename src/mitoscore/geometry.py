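"""Polygon helpers: coercion, rasterization, point membership.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``;
* polygon vertices are ``(x, y) = (col, row)`` pairs, matching the Labelme
  annotation dialect;
* a pixel belongs to a polygon when its centre ``(col, row)`` intersects the
  closed polygon — boundary points count as inside.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import EmptyRegionError

__all__ = ["as_polygon", "polygon_mask", "points_in_polygon"]


def as_polygon(region: Polygon | Sequence[Sequence[float]]) -> Polygon:
    """Coerce a vertex sequence (or pass through a shapely Polygon)."""
    if isinstance(region, Polygon):
        poly = region
    else:
        poly = Polygon([(float(x), float(y)) for x, y in region])
    if poly.area == 0:
        raise EmptyRegionError("polygon region has zero area")
    return poly


def polygon_mask(region: Polygon | Sequence[Sequence[float]],
                 shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of the pixels whose centres fall inside ``region``.

    Boundary pixels are included. Only the polygon's bounding box is tested,
    so the cost scales with the region, not the image.
    """
    poly = as_polygon(region)
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor(minx)), 0)
    c1 = min(int(np.ceil(maxx)) + 1, w)
    r0 = max(int(np.floor(miny)), 0)
    r1 = min(int(np.ceil(maxy)) + 1, h)
    out = np.zeros(shape, dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return out
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = shapely.intersects_xy(poly, cc.ravel(), rr.ravel())
    out[r0:r1, c0:c1] = inside.reshape(rr.shape)
    return out


def points_in_polygon(points: Sequence[tuple[float, float]],
                      region: Polygon | Sequence[Sequence[float]]) -> np.ndarray:
    """Membership of ``(row, col)`` points in a polygon (boundary inclusive)."""
    poly = as_polygon(region)
    if len(points) == 0:
        return np.zeros(0, dtype=bool)
    pts = np.asarray(points, dtype=float)
    return shapely.intersects_xy(poly, pts[:, 1], pts[:, 0])
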