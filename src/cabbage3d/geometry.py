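"""Computational-geometry primitives backing the trait extractors.

Convex hulls are delegated to Qhull (``scipy.spatial.ConvexHull``); the
quantities derived from them — tetrahedron-decomposition volume, triangle-sum
surface area, shoelace polygon area, pairwise-distance extrema, rotating
calipers, and the exact Welzl minimum enclosing circle — are computed here
because their exact definitions (absolute-value tetrahedra referenced to an
interior point, vertex-pairwise extrema, MEC on the projected points) are what
the downstream shape descriptors mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateGeometryError

__all__ = [
    "Contour2D",
    "ConvexHull3D",
    "convex_contour_2d",
    "polygon_area",
    "convex_hull_3d",
    "hull_volume_surface",
    "pairwise_extremes",
    "calipers_diameter_width",
    "min_enclosing_circle",
]


@dataclass
class Contour2D:
    """Ordered convex-polygon outline in a named coordinate plane."""

    points: np.ndarray  # (m, 2), counterclockwise, strictly convex
    plane: str = "xy"

    @property
    def n_vertices(self) -> int:
        return self.points.shape[0]


@dataclass
class ConvexHull3D:
    """Watertight triangulated convex hull with an interior reference point."""

    vertices: np.ndarray   # (m, 3)
    faces: np.ndarray      # (f, 3) indices into vertices
    interior: np.ndarray   # reference point for tetrahedron decomposition


def convex_contour_2d(points: np.ndarray, plane: str = "xy") -> Contour2D:
    """Counterclockwise convex hull of an (n, 2) point set."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points for a 2D contour")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate 2D point set: {exc}") from exc
    return Contour2D(pts[hull.vertices], plane)  # Qhull returns CCW order in 2D


def polygon_area(contour: Contour2D | np.ndarray) -> float:
    """Shoelace area of a simple polygon given by ordered vertices."""
    pts = contour.points if isinstance(contour, Contour2D) else np.asarray(contour)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def convex_hull_3d(points: np.ndarray) -> ConvexHull3D:
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        raise DegenerateGeometryError("need at least 4 points for a 3D hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate 3D point set: {exc}") from exc
    verts = pts[hull.vertices]
    remap = {v: i for i, v in enumerate(hull.vertices)}
    faces = np.array([[remap[i] for i in simplex] for simplex in hull.simplices])
    return ConvexHull3D(verts, faces, verts.mean(axis=0))


def hull_volume_surface(hull: ConvexHull3D) -> tuple[float, float]:
    """Volume and surface area of a triangulated convex hull.

    Volume sums ``|r_i . (r_j x r_k)| / 6`` over faces with the vertex vectors
    referenced to an interior point, so every tetrahedron contributes
    positively; surface sums the triangle areas ``|(r_j - r_i) x (r_k - r_i)| / 2``.
    """
    tri = hull.vertices[hull.faces]  # (f, 3, 3)
    r = tri - hull.interior
    vol = np.abs(np.einsum("fi,fi->f", r[:, 0],
                           np.cross(r[:, 1], r[:, 2]))).sum() / 6.0
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    area = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1).sum()
    return float(vol), float(area)


def pairwise_extremes(points: np.ndarray) -> tuple[float, float]:
    """(max, min) pairwise Euclidean distance over a point set (n >= 2)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise DegenerateGeometryError("need at least 2 points for pairwise distances")
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    iu = np.triu_indices(pts.shape[0], k=1)
    vals = d[iu]
    return float(vals.max()), float(vals.min())


def calipers_diameter_width(contour: Contour2D) -> tuple[float, float]:
    """Rotating-calipers diameter (max extent) and width (min extent).

    Both are computed as support-function extrema over the edge directions of
    the convex polygon, which is exact for convex input.
    """
    pts = contour.points
    m = pts.shape[0]
    if m < 2:
        raise DegenerateGeometryError("contour needs at least 2 vertices")
    dmax, _ = pairwise_extremes(pts)
    width = np.inf
    for i in range(m):
        a, b = pts[i], pts[(i + 1) % m]
        edge = b - a
        norm = np.linalg.norm(edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        proj = (pts - a) @ normal
        width = min(width, proj.max() - proj.min())
    return float(dmax), float(width)


# ---------------------------------------------------------------------------
# Exact minimum enclosing circle (Welzl, move-to-front, iterative growth)

def min_enclosing_circle(points: np.ndarray, tol: float = 1e-12
                         ) -> tuple[np.ndarray, float]:
    """Exact smallest circle enclosing 2D ``points``; returns (center, radius).

    Incremental Welzl-style construction: points are processed in a fixed
    order and whenever a point falls outside the current circle it becomes a
    boundary point and the circle is rebuilt over the prefix.  Runs in
    expected linear time on shuffled input; here the order is deterministic
    (a fixed stride permutation) so results are reproducible.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n == 0:
        raise DegenerateGeometryError("no points for enclosing circle")
    if n == 1:
        return pts[0].copy(), 0.0
    # deterministic pseudo-shuffle to dodge adversarial orderings
    order = np.argsort((np.arange(n) * 2654435761) % (2 ** 32), kind="stable")
    p = pts[order]

    def circle_two(a, b):
        c = (a + b) / 2.0
        return c, float(np.linalg.norm(a - c))

    def circle_three(a, b, c):
        # circumcircle; returns None for (near-)collinear triples
        d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-14 * max(1.0, np.abs([a, b, c]).max() ** 2):
            return None
        a2, b2, c2 = (a ** 2).sum(), (b ** 2).sum(), (c ** 2).sum()
        ux = (a2 * (b[1] - c[1]) + b2 * (c[1] - a[1]) + c2 * (a[1] - b[1])) / d
        uy = (a2 * (c[0] - b[0]) + b2 * (a[0] - c[0]) + c2 * (b[0] - a[0])) / d
        center = np.array([ux, uy])
        return center, float(np.linalg.norm(a - center))

    def in_circle(circ, q, eps):
        c, r = circ
        return np.linalg.norm(q - c) <= r * (1 + eps) + eps

    def mec_one_boundary(prefix, q):
        circ = circle_two(prefix[0], q)
        for j in range(1, len(prefix)):
            if not in_circle(circ, prefix[j], tol):
                circ = mec_two_boundary(prefix[: j + 1], prefix[j], q)
        return circ

    def mec_two_boundary(prefix, q1, q2):
        # smallest circle through q1 and q2 enclosing prefix: track the best
        # circumcircle candidate on each side of the chord q1-q2
        base = circle_two(q1, q2)
        pq = q2 - q1
        left = right = None
        left_x = right_x = 0.0
        for r in prefix:
            if in_circle(base, r, tol):
                continue
            cross = pq[0] * (r[1] - q1[1]) - pq[1] * (r[0] - q1[0])
            c3 = circle_three(q1, q2, r)
            if c3 is None:
                continue
            cx = pq[0] * (c3[0][1] - q1[1]) - pq[1] * (c3[0][0] - q1[0])
            if cross > 0 and (left is None or cx > left_x):
                left, left_x = c3, cx
            elif cross < 0 and (right is None or cx < right_x):
                right, right_x = c3, cx
        if left is None and right is None:
            return base
        if left is None:
            return right
        if right is None:
            return left
        return left if left[1] <= right[1] else right

    circ = circle_two(p[0], p[1])
    for i in range(2, n):
        if not in_circle(circ, p[i], tol):
            circ = mec_one_boundary(p[:i], p[i])
    center, radius = circ
    # tighten: exact radius is the max distance to the final center
    radius = float(np.linalg.norm(pts - center, axis=1).max())
    return center, radius


def _farthest_pair(pts: np.ndarray) -> tuple[int, int]:
    diff = pts[:, None, :] - pts[None, :, :]
    d = (diff ** 2).sum(-1)
    return np.unravel_index(np.argmax(d), d.shape)  # type: ignore[return-value]
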