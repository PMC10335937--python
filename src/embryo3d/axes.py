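"""Anatomical 1D coordinates: principal-curve AP arclength, convex-hull DV
distance, spatial binning, boundary distances and pseudotime/space pairs.

The anterior–posterior (AP) coordinate of an elongated structure such as the
neural tube is the arclength along a principal curve fitted through the bead
cloud; the dorso-ventral (DV) coordinate of a tube cross-section is each
bead's distance to the convex hull of the bead set.  Both are binned into
equal-width spatial bins (25 along AP, 8 along DV by default) for profiling
and trend testing.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from shapely.geometry import LineString, Polygon

__all__ = [
    "principal_curve_coordinate",
    "dv_coordinate",
    "bin_coordinate",
    "boundary_select",
    "pseudotime_space_pairs",
]


def _project_to_polyline(points: np.ndarray, verts: np.ndarray):
    """Project points onto a polyline; return (arclength, distance)."""
    seg_start = verts[:-1]                      # (m, d)
    seg_vec = verts[1:] - verts[:-1]            # (m, d)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    keep = seg_len > 1e-12
    seg_start, seg_vec, seg_len = seg_start[keep], seg_vec[keep], seg_len[keep]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    diff = points[:, None, :] - seg_start[None, :, :]          # (n, m, d)
    t = np.einsum("nmd,md->nm", diff, seg_vec) / seg_len**2
    t = np.clip(t, 0.0, 1.0)
    foot = seg_start[None] + t[..., None] * seg_vec[None]
    d2 = ((points[:, None, :] - foot) ** 2).sum(axis=2)
    j = np.argmin(d2, axis=1)
    n = np.arange(len(points))
    arclen = cum[j] + t[n, j] * seg_len[j]
    return arclen, np.sqrt(d2[n, j])


def principal_curve_coordinate(
    points: np.ndarray,
    smoothing_span: float = 0.3,
    anterior_landmark: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> np.ndarray:
    """Arclength coordinate (µm) of each bead along a fitted principal curve.

    The curve is fitted by the classic projection/averaging alternation:
    initialize with the first principal component, smooth each spatial
    coordinate against the current arclength (lowess with fraction
    ``smoothing_span``), re-project the beads onto the smoothed polyline, and
    repeat.  The orientation is fixed so the bead nearest
    ``anterior_landmark`` gets coordinate 0 (default landmark: the first
    principal-component minimum end).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    points = np.asarray(points, dtype=float)
    if len(points) < 10:
        raise ValueError("need at least 10 beads for a principal curve")
    if np.allclose(points, points[0]):
        raise ValueError("beads are all coincident")
    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center, full_matrices=False)
    lam = (points - center) @ vt[0]

    converged = False
    for _ in range(max_iter):
        order = np.argsort(lam, kind="stable")
        lam_sorted = lam[order]
        curve = np.column_stack(
            [
                lowess(points[order, d], lam_sorted, frac=smoothing_span,
                       return_sorted=False)
                for d in range(points.shape[1])
            ]
        )
        # collapse duplicate lambda values to keep the polyline simple
        uniq, inv = np.unique(np.round(lam_sorted, 9), return_inverse=True)
        verts = np.array([curve[inv == i].mean(axis=0) for i in range(len(uniq))])
        if len(verts) < 2:
            break
        new_lam, _ = _project_to_polyline(points, verts)
        scale = max(np.ptp(new_lam), 1e-12)
        if np.max(np.abs(new_lam - new_lam.mean() - (lam - lam.mean()))) < tol * scale:
            lam = new_lam
            converged = True
            break
        lam = new_lam
    if not converged:
        warnings.warn("principal curve did not converge; returning last iterate")

    lam = lam - lam.min()
    if anterior_landmark is not None:
        landmark = np.asarray(anterior_landmark, dtype=float)
        nearest = np.argmin(((points - landmark) ** 2).sum(axis=1))
        if lam[nearest] > lam.max() / 2:
            lam = lam.max() - lam
    return lam


def dv_coordinate(
    points: np.ndarray, n_bins: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Distance of each bead to the convex hull boundary, with bin ids.

    Returns ``(distance_um, bin_id)``; bins are equal-width over
    [0, max distance] (all-boundary sets collapse to bin 0).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise ValueError("need at least 4 beads")
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ValueError(f"degenerate hull: {exc}") from exc
    boundary = Polygon(points[hull.vertices]).exterior
    import shapely

    dist = shapely.distance(boundary, shapely.points(points))
    bins = bin_coordinate(dist, n_bins) if dist.max() > 0 else np.zeros(len(points), int)
    return dist, bins


def bin_coordinate(coords: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width half-open bins over [min, max]; the last bin is closed.

    Defaults used upstream: 25 bins along AP, 8 along DV.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    lo, hi = coords.min(), coords.max()
    if hi == lo:
        warnings.warn("zero coordinate range; all beads in bin 0")
        return np.zeros(len(coords), dtype=int)
    idx = ((coords - lo) / (hi - lo) * n_bins).astype(int)
    return np.minimum(idx, n_bins - 1)


def boundary_select(
    points: np.ndarray,
    boundary: np.ndarray,
    max_dist: float = 300.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Beads within ``max_dist`` µm of a boundary polyline.

    ``boundary`` is an (m, 2) vertex array (m >= 2); distances are true
    point-to-segment distances (an endpoint is the nearest feature beyond the
    segment ends).  Returns ``(indices, distance_um)`` of the selected beads,
    the distance being the trend-test coordinate downstream.
    """
    boundary = np.asarray(boundary, dtype=float)
    if boundary.ndim != 2 or len(boundary) < 2:
        raise ValueError("boundary polyline needs at least 2 vertices")
    import shapely

    line = LineString(boundary)
    dist = shapely.distance(line, shapely.points(np.asarray(points, dtype=float)[:, :2]))
    keep = np.flatnonzero(dist <= max_dist)
    return keep, dist[keep]


def pseudotime_space_pairs(
    points: np.ndarray,
    pseudotime: np.ndarray,
    cell_state: np.ndarray | None = None,
    state: str | None = None,
) -> np.ndarray:
    """All unordered within-state bead pairs as (spatial distance µm,
    pseudotime difference) rows — n(n−1)/2 of them — for 2D density
    summaries of how transcriptional change relates to physical distance.
    """
    points = np.asarray(points, dtype=float)
    pseudotime = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(pseudotime)):
        raise ValueError("pseudotime values must be finite")
    if cell_state is not None and state is not None:
        m = np.asarray(cell_state) == state
        points, pseudotime = points[m], pseudotime[m]
    if len(points) < 2:
        raise ValueError("need at least 2 beads in the state")
    d_space = pdist(points)
    d_time = pdist(pseudotime[:, None], metric="cityblock")
    return np.column_stack([d_space, d_time])
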