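"""Planar geometry primitives shared by the EM-morphometry and boundary modules.

All routines use exact orthogonal projection onto polyline segments (no
sampling) and operate on float64 arrays of shape (n, 2).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "point_to_polyline_distance",
    "polyline_arc_lengths",
    "subpolyline",
    "point_in_polygon",
    "signed_polygon_distance",
    "polyline_is_simple",
]


def _as_vertices(vertices) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
        raise ValueError("polyline must be an (n>=2, 2) array of points")
    return v


def point_to_polyline_distance(point, vertices) -> float:
    """Minimum Euclidean distance from ``point`` to an open polyline.

    Each segment contributes the distance to the orthogonal projection of
    the point, clamped to the segment; the minimum over segments is exact.

    Raises
    ------
    ValueError
        If the polyline is degenerate (all vertices coincide).
    """
    v = _as_vertices(vertices)
    p = np.asarray(point, dtype=float)
    a, b = v[:-1], v[1:]
    d = b - a
    seg_len2 = np.einsum("ij,ij->i", d, d)
    if not np.any(seg_len2 > 0):
        raise ValueError("degenerate polyline: all points identical")
    t = np.clip(np.einsum("ij,ij->i", p - a, d) / np.where(seg_len2 > 0, seg_len2, 1.0), 0.0, 1.0)
    closest = a + t[:, None] * d
    return float(np.sqrt(np.min(np.einsum("ij,ij->i", p - closest, p - closest))))


def polyline_arc_lengths(vertices) -> np.ndarray:
    """Cumulative arc length at each vertex, starting at 0."""
    v = _as_vertices(vertices)
    seg = np.sqrt(np.sum(np.diff(v, axis=0) ** 2, axis=1))
    return np.concatenate([[0.0], np.cumsum(seg)])


def _point_at_arc(vertices: np.ndarray, arcs: np.ndarray, s: float) -> np.ndarray:
    i = int(np.searchsorted(arcs, s, side="right")) - 1
    i = min(max(i, 0), len(vertices) - 2)
    seg = arcs[i + 1] - arcs[i]
    t = 0.0 if seg == 0 else (s - arcs[i]) / seg
    return vertices[i] + t * (vertices[i + 1] - vertices[i])


def point_at_arc(vertices, s: float) -> np.ndarray:
    """Point at arc-length position ``s`` along the polyline."""
    v = _as_vertices(vertices)
    arcs = polyline_arc_lengths(v)
    return _point_at_arc(v, arcs, float(np.clip(s, 0.0, arcs[-1])))


def tangent_at_arc(vertices, s: float) -> np.ndarray:
    """Unit tangent of the segment containing arc position ``s``."""
    v = _as_vertices(vertices)
    arcs = polyline_arc_lengths(v)
    s = float(np.clip(s, 0.0, arcs[-1]))
    i = int(np.searchsorted(arcs, s, side="right")) - 1
    i = min(max(i, 0), len(v) - 2)
    d = v[i + 1] - v[i]
    n = np.hypot(*d)
    if n == 0:
        raise ValueError("zero-length segment at requested arc position")
    return d / n


def subpolyline(vertices, start_arc: float, end_arc: float) -> np.ndarray:
    """Contiguous sub-polyline between two arc-length positions.

    End points are interpolated exactly; interior vertices are kept.
    """
    v = _as_vertices(vertices)
    arcs = polyline_arc_lengths(v)
    if not (0.0 <= start_arc < end_arc <= arcs[-1] + 1e-9):
        raise ValueError(
            f"arc span [{start_arc}, {end_arc}] outside polyline length {arcs[-1]:.6g}"
        )
    end_arc = min(end_arc, arcs[-1])
    p0 = _point_at_arc(v, arcs, start_arc)
    p1 = _point_at_arc(v, arcs, end_arc)
    interior = v[(arcs > start_arc + 1e-12) & (arcs < end_arc - 1e-12)]
    pts = np.vstack([p0, interior, p1]) if len(interior) else np.vstack([p0, p1])
    # drop consecutive duplicates
    keep = np.concatenate([[True], np.any(np.abs(np.diff(pts, axis=0)) > 1e-12, axis=1)])
    out = pts[keep]
    if len(out) < 2:
        out = np.vstack([p0, p1])
    return out


def point_in_polygon(point, polygon) -> bool:
    """Even-odd (ray-crossing) point-in-polygon test.

    Points lying exactly on an edge or vertex count as inside, matching the
    convention that a punctum on the boundary has signed distance 0 (inside).
    """
    poly = _as_vertices(polygon)
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    x, y = float(point[0]), float(point[1])
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # on-edge check (collinear and within bbox)
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 * max(1.0, abs(x2 - x1) + abs(y2 - y1)):
            if min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
                return True
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < x_int:
                inside = not inside
    return inside


def signed_polygon_distance(point, polygon) -> float:
    """Signed distance from a point to a closed polygon boundary.

    Negative inside (even-odd rule; boundary counts as inside), positive
    outside; magnitude is the exact minimum distance to the polygon edges.
    """
    poly = _as_vertices(polygon)
    closed = poly if np.allclose(poly[0], poly[-1]) else np.vstack([poly, poly[0]])
    d = point_to_polyline_distance(point, closed)
    return -d if point_in_polygon(point, poly) else d


def _cross2(a, b) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _segments_intersect(p1, p2, p3, p4) -> bool:
    d1 = _cross2(p4 - p3, p1 - p3)
    d2 = _cross2(p4 - p3, p2 - p3)
    d3 = _cross2(p2 - p1, p3 - p1)
    d4 = _cross2(p2 - p1, p4 - p1)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def polyline_is_simple(vertices) -> bool:
    """True if no two non-adjacent segments of the polyline intersect."""
    v = _as_vertices(vertices)
    n = len(v) - 1
    for i in range(n):
        for j in range(i + 2, n):
            if _segments_intersect(v[i], v[i + 1], v[j], v[j + 1]):
                return False
    return True
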