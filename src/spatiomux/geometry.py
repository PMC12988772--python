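"""Polygon primitives used throughout the package.

All polygons are simple rings stored as ``(n, 2)`` float arrays of ``(x, y)``
vertices in micrometres, implicitly closed (the first vertex is not
repeated at the end). Writers that target formats requiring explicit ring
closure (GeoJSON) append the closing vertex on export.

Point-in-polygon uses the even-odd rule with boundary points counting as
inside; for the simple rings handled here this matches shapely's ``covers``
predicate, which is what the implementation delegates to.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

from ._exceptions import InvalidPolygonError

__all__ = [
    "as_ring",
    "polygon_area",
    "points_in_polygon",
    "ring_to_shapely",
]


def as_ring(vertices) -> np.ndarray:
    """Normalize *vertices* to an implicitly closed ``(n, 2)`` float ring.

    Accepts any sequence of (x, y) pairs. An explicitly closed ring
    (first vertex repeated last) is stripped of the duplicate. Raises
    :class:`InvalidPolygonError` if fewer than three distinct vertices remain.
    """
    ring = np.asarray(vertices, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2:
        raise InvalidPolygonError(f"expected (n, 2) vertex array, got shape {ring.shape}")
    if len(ring) >= 2 and np.array_equal(ring[0], ring[-1]):
        ring = ring[:-1]
    if len(np.unique(ring, axis=0)) < 3:
        raise InvalidPolygonError("polygon needs at least 3 distinct vertices")
    if not np.all(np.isfinite(ring)):
        raise InvalidPolygonError("polygon vertices must be finite")
    return ring


def ring_to_shapely(vertices) -> _ShapelyPolygon:
    """Shapely polygon for an implicitly closed ring."""
    return _ShapelyPolygon(as_ring(vertices))


def polygon_area(vertices) -> float:
    """Unsigned (shoelace) area of a polygon ring, in µm².

    Vertex orientation does not matter; the absolute value is returned.
    """
    ring = as_ring(vertices)
    x, y = ring[:, 0], ring[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def points_in_polygon(points, vertices) -> np.ndarray:
    """Boolean mask of points inside the polygon (boundary counts as inside).

    Parameters
    ----------
    points : sequence of (x, y) pairs, shape ``(m, 2)``; may be empty.
    vertices : polygon ring.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return np.zeros(0, dtype=bool)
    poly = ring_to_shapely(vertices)
    shapely.prepare(poly)
    return shapely.covers(poly, shapely.points(pts[:, 0], pts[:, 1]))
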