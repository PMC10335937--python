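"""Alpha shapes in 2D and 3D from Delaunay triangulations.

The alpha shape at scale ``alpha`` keeps every Delaunay simplex whose
circumradius is at most ``alpha``; as alpha grows it converges to the convex
hull, while small alpha follows concavities and opens holes.  The 2D variant
returns a shapely (multi)polygon; the 3D variant returns the total volume of
the kept tetrahedra (what the volume-based scores need) without building an
explicit surface.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

__all__ = ["alpha_shape_2d", "alpha_shape_volume_3d", "convex_hull_volume"]


def _circumradius_2d(pts: np.ndarray) -> np.ndarray:
    """Circumradii for (n, 3, 2) triangle vertex arrays."""
    a = np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1)
    b = np.linalg.norm(pts[:, 1] - pts[:, 2], axis=1)
    c = np.linalg.norm(pts[:, 2] - pts[:, 0], axis=1)
    s = (a + b + c) / 2
    area2 = np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None)
    area = np.sqrt(area2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (4 * area)
    r[~np.isfinite(r)] = np.inf
    return r


def alpha_shape_2d(points: np.ndarray, alpha: float) -> Polygon | MultiPolygon:
    """Alpha shape of 2D points; empty polygon on degenerate input."""
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        return Polygon()
    try:
        tri = Delaunay(points)
    except QhullError:
        return Polygon()
    simplices = tri.simplices
    keep = _circumradius_2d(points[simplices]) <= alpha
    if not keep.any():
        return Polygon()
    polys = [Polygon(points[s]) for s in simplices[keep]]
    merged = unary_union(polys)
    return merged


def _circumradius_3d(pts: np.ndarray) -> np.ndarray:
    """Circumradii for (n, 4, 3) tetrahedron vertex arrays."""
    # solve |x - v0|^2 = |x - vi|^2 for the circumcenter x
    v0 = pts[:, 0]
    rows = pts[:, 1:] - v0[:, None, :]          # (n, 3, 3)
    rhs = 0.5 * (rows**2).sum(axis=2)           # (n, 3)
    det = np.linalg.det(rows)
    out = np.full(len(pts), np.inf)
    ok = np.abs(det) > 1e-12
    if ok.any():
        sol = np.linalg.solve(rows[ok], rhs[ok][..., None])[..., 0]
        out[ok] = np.linalg.norm(sol, axis=1)
    return out


def _tet_volumes(pts: np.ndarray) -> np.ndarray:
    v0 = pts[:, 0]
    mat = pts[:, 1:] - v0[:, None, :]
    return np.abs(np.linalg.det(mat)) / 6.0


def alpha_shape_volume_3d(points: np.ndarray, alpha: float) -> float:
    """Volume (µm³) of the 3D alpha shape: sum of kept-tetrahedron volumes.

    Returns 0.0 on degenerate input (fewer than 4 points, coplanar set, or no
    tetrahedron within scale).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        return 0.0
    try:
        tri = Delaunay(points)
    except QhullError:
        return 0.0
    pts = points[tri.simplices]
    keep = _circumradius_3d(pts) <= alpha
    if not keep.any():
        return 0.0
    return float(_tet_volumes(pts[keep]).sum())


def convex_hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume (3D) / area (2D); 0.0 when degenerate."""
    points = np.asarray(points, dtype=float)
    if len(points) <= points.shape[1]:
        return 0.0
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return 0.0
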