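"""From registered stack to 3D tissue geometry: masks, interpolation, volumes.

Each tissue's footprint on a section is an alpha shape of its beads (convex
hull as fallback).  Between sections, footprints are morphed by linear
interpolation of their signed-distance fields — the standard contour-morphing
interpolant, which handles splitting/merging lobes gracefully.  The tissue
volume integrates mask area over z across real and virtual (interpolated)
slices, with end slices extending half a section thickness beyond their
centers.  Holes enclosed by the alpha shape (e.g. a lumen) are excluded from
area; pass ``alpha=None`` for convex-hull masks if cavities should count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union

from .alpha_shapes import alpha_shape_2d
from .io_model import EmbryoStack, SpatialArray

__all__ = [
    "TissueMask",
    "VolumeReport",
    "tissue_mask",
    "interpolate_masks",
    "tissue_volume",
    "export_mesh",
]


@dataclass
class TissueMask:
    """Polygonal footprint of one tissue on one (registered) slice plane."""

    z: float
    tissue: str
    geometry: Polygon | MultiPolygon

    @property
    def area(self) -> float:
        return float(self.geometry.area)

    @property
    def is_empty(self) -> bool:
        return self.geometry.is_empty or self.geometry.area == 0.0


@dataclass
class VolumeReport:
    tissue: str
    volume_um3: float
    n_beads: int
    n_slices: int
    method: str

    @property
    def volume_1e3_um3(self) -> float:
        """Volume in the 10^3 µm^3 reporting unit."""
        return self.volume_um3 / 1e3


def tissue_mask(
    array: SpatialArray,
    tissue: str,
    alpha: float | None = 50.0,
    min_beads: int = 10,
    z: float = 0.0,
    coords: np.ndarray | None = None,
    bead_radius: float = 0.0,
) -> TissueMask:
    """Alpha-shape footprint of one tissue's beads on a section.

    ``coords`` overrides the section's stored coordinates (pass registered
    coordinates when masking a stack).  Falls back to the convex hull when the
    alpha shape degenerates; fewer than ``min_beads`` beads give an empty
    mask.  A positive ``bead_radius`` buffers the footprint outward by that
    much: beads are capture disks, not points, so the shape through their
    centers sits about one bead radius inside the tissue boundary.
    """
    pts = (coords if coords is not None else array.coords)[array.cell_state == tissue]
    if len(pts) < min_beads:
        return TissueMask(z=z, tissue=tissue, geometry=Polygon())
    geom: Polygon | MultiPolygon
    if alpha is None:
        geom = Polygon()
    else:
        geom = alpha_shape_2d(pts, alpha)
    if geom.is_empty or geom.area == 0.0:
        hull = Polygon(pts[_hull_vertices(pts)]) if _hull_vertices(pts) is not None else Polygon()
        if hull.is_empty or hull.area == 0.0:
            warnings.warn(f"degenerate geometry for tissue {tissue!r}; empty mask")
            return TissueMask(z=z, tissue=tissue, geometry=Polygon())
        geom = hull
    if bead_radius > 0:
        geom = geom.buffer(bead_radius)
    return TissueMask(z=z, tissue=tissue, geometry=geom)


def _hull_vertices(pts: np.ndarray):
    from scipy.spatial import ConvexHull, QhullError

    try:
        return ConvexHull(pts).vertices
    except QhullError:
        return None


# ---------------------------------------------------------------------------
# signed-distance interpolation


def _signed_distance_grid(
    geom: Polygon | MultiPolygon,
    xs: np.ndarray,
    ys: np.ndarray,
    empty_level: float,
) -> np.ndarray:
    """Signed distance to the boundary (negative inside) sampled on a grid."""
    import shapely

    if geom.is_empty:
        return np.full((len(ys), len(xs)), empty_level)
    XX, YY = np.meshgrid(xs, ys)
    pts = shapely.points(np.column_stack([XX.ravel(), YY.ravel()]))
    d = shapely.distance(geom.boundary, pts)
    inside = shapely.contains_xy(geom, XX.ravel(), YY.ravel())
    return np.where(inside, -d, d).reshape(XX.shape)


def _polygonize_level(field: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> Polygon | MultiPolygon:
    """Zero level set of a signed-distance grid as a shapely polygon."""
    from skimage import measure

    polys = []
    for contour in measure.find_contours(field, 0.0):
        if len(contour) < 3:
            continue
        # contour is (row=iy, col=ix) in index space; map to µm
        x = np.interp(contour[:, 1], np.arange(len(xs)), xs)
        y = np.interp(contour[:, 0], np.arange(len(ys)), ys)
        poly = Polygon(np.column_stack([x, y]))
        if poly.is_valid and poly.area > 0:
            polys.append(poly)
    if not polys:
        return Polygon()
    # outer rings minus inner rings: union with symmetric-difference semantics
    polys.sort(key=lambda p: p.area, reverse=True)
    result = polys[0]
    for p in polys[1:]:
        result = result.symmetric_difference(p)
    return result if not result.is_empty else Polygon()


def interpolate_masks(
    maskA: TissueMask,
    maskB: TissueMask,
    n_virtual: int,
    grid_pitch: float = 10.0,
) -> list[TissueMask]:
    """Morph between two footprints via signed-distance interpolation.

    Returns ``n_virtual`` masks at evenly spaced intermediate z.  An
    empty/nonempty pair shrinks the nonempty footprint toward nothing by
    offsetting its distance field.
    """
    if n_virtual < 0:
        raise ValueError("n_virtual must be >= 0")
    if n_virtual == 0:
        return []
    if maskA.z >= maskB.z:
        raise ValueError("maskA must lie below maskB in z")
    if maskA.is_empty and maskB.is_empty:
        zs = np.linspace(maskA.z, maskB.z, n_virtual + 2)[1:-1]
        return [TissueMask(z=float(z), tissue=maskA.tissue, geometry=Polygon()) for z in zs]

    geoms = [g for g in (maskA.geometry, maskB.geometry) if not g.is_empty]
    xmin, ymin, xmax, ymax = unary_union(geoms).bounds
    pad = 2 * grid_pitch
    xs = np.arange(xmin - pad, xmax + pad + grid_pitch, grid_pitch)
    ys = np.arange(ymin - pad, ymax + pad + grid_pitch, grid_pitch)

    fA = _signed_distance_grid(maskA.geometry, xs, ys, empty_level=np.nan)
    fB = _signed_distance_grid(maskB.geometry, xs, ys, empty_level=np.nan)
    # empty side: shrink the nonempty field toward empty by pushing its level
    # below the field minimum (so the zero set vanishes at the empty end)
    if maskA.is_empty:
        fA = fB - (np.nanmin(fB) - grid_pitch)
    if maskB.is_empty:
        fB = fA - (np.nanmin(fA) - grid_pitch)

    out = []
    zs = np.linspace(maskA.z, maskB.z, n_virtual + 2)[1:-1]
    for z in zs:
        w = (z - maskA.z) / (maskB.z - maskA.z)
        field = (1 - w) * fA + w * fB
        out.append(
            TissueMask(z=float(z), tissue=maskA.tissue, geometry=_polygonize_level(field, xs, ys))
        )
    return out


def tissue_volume(
    stack: EmbryoStack,
    tissue: str,
    n_virtual_per_gap: int = 4,
    alpha: float | None = 50.0,
    min_beads: int = 10,
    bead_radius: float = 5.0,
) -> VolumeReport:
    """Tissue volume from stacked (real + interpolated virtual) footprints.

    volume = Σ area_i × slab_i with slab boundaries halfway between
    successive slice centers; the first and last contributing slices extend
    half a section thickness beyond their centers.  ``bead_radius`` (default
    half the 10-µm bead pitch) corrects the inward bias of footprints drawn
    through bead centers.
    """
    zs = stack.z_positions
    masks: list[TissueMask] = []
    n_beads = 0
    for i, arr in enumerate(stack.arrays):
        coords = stack.registered_coords(i)
        m = tissue_mask(arr, tissue, alpha=alpha, min_beads=min_beads, z=float(zs[i]),
                        coords=coords, bead_radius=bead_radius)
        masks.append(m)
        n_beads += int((arr.cell_state == tissue).sum())
    contributing = [m for m in masks if not m.is_empty]
    if not contributing:
        warnings.warn(f"tissue {tissue!r} absent from all slices; volume 0")
        return VolumeReport(tissue=tissue, volume_um3=0.0, n_beads=n_beads,
                            n_slices=0, method="stacked-masks")

    # virtual slices between consecutive real slices (only around the
    # contributing range — interpolating through all-empty spans adds nothing)
    first = masks.index(contributing[0])
    last = masks.index(contributing[-1])
    all_masks: list[TissueMask] = []
    for i in range(first, last + 1):
        all_masks.append(masks[i])
        if i < last and n_virtual_per_gap > 0:
            all_masks.extend(interpolate_masks(masks[i], masks[i + 1], n_virtual_per_gap))
    all_masks.sort(key=lambda m: m.z)

    z = np.array([m.z for m in all_masks])
    area = np.array([m.area for m in all_masks])
    thickness = stack.arrays[first].thickness
    if len(z) == 1:
        vol = float(area[0] * thickness)
    else:
        mid = (z[1:] + z[:-1]) / 2
        lower = np.concatenate([[z[0] - thickness / 2], mid])
        upper = np.concatenate([mid, [z[-1] + thickness / 2]])
        vol = float((area * (upper - lower)).sum())
    return VolumeReport(
        tissue=tissue,
        volume_um3=vol,
        n_beads=n_beads,
        n_slices=len(contributing),
        method="stacked-masks+sdf-interp",
    )


def export_mesh(
    stack: EmbryoStack,
    tissue: str,
    path,
    alpha: float | None = 50.0,
    n_virtual_per_gap: int = 4,
    voxel_pitch: float = 10.0,
):
    """Triangulated surface of the tissue as an OBJ file.

    The stacked footprints are voxelized (with virtual interpolated slices
    filling the gaps), the surface extracted by marching cubes and exported
    via trimesh.  Returns the mesh object.
    """
    import trimesh
    from skimage import measure

    zs = stack.z_positions
    masks = []
    for i, arr in enumerate(stack.arrays):
        m = tissue_mask(arr, tissue, alpha=alpha, z=float(zs[i]),
                        coords=stack.registered_coords(i))
        if not m.is_empty:
            masks.append(m)
    if not masks:
        raise ValueError(f"tissue {tissue!r} has no nonempty footprint")
    full: list[TissueMask] = []
    for i, m in enumerate(masks):
        full.append(m)
        if i + 1 < len(masks) and n_virtual_per_gap > 0:
            full.extend(interpolate_masks(m, masks[i + 1], n_virtual_per_gap))
    full.sort(key=lambda m: m.z)

    bounds = unary_union([m.geometry for m in full]).bounds
    xmin, ymin, xmax, ymax = bounds
    pad = 2 * voxel_pitch
    xs = np.arange(xmin - pad, xmax + pad, voxel_pitch)
    ys = np.arange(ymin - pad, ymax + pad, voxel_pitch)
    z0 = full[0].z - stack.arrays[0].thickness
    z1 = full[-1].z + stack.arrays[0].thickness
    zs_vox = np.arange(z0, z1 + voxel_pitch, voxel_pitch)

    import shapely

    vol = np.zeros((len(zs_vox), len(ys), len(xs)), dtype=bool)
    mask_z = np.array([m.z for m in full])
    XX, YY = np.meshgrid(xs, ys)
    for iz, zv in enumerate(zs_vox):
        if zv < mask_z[0] - stack.arrays[0].thickness / 2 or \
           zv > mask_z[-1] + stack.arrays[0].thickness / 2:
            continue
        j = int(np.clip(np.searchsorted(mask_z, zv), 0, len(full) - 1))
        if j > 0 and abs(mask_z[j - 1] - zv) < abs(mask_z[j] - zv):
            j -= 1
        geom = full[j].geometry
        if geom.is_empty:
            continue
        vol[iz] = shapely.contains_xy(geom, XX.ravel(), YY.ravel()).reshape(XX.shape)

    verts, faces, _, _ = measure.marching_cubes(vol.astype(float), level=0.5)
    # index space (z, y, x) -> µm
    verts_um = np.column_stack(
        [
            np.interp(verts[:, 2], np.arange(len(xs)), xs),
            np.interp(verts[:, 1], np.arange(len(ys)), ys),
            np.interp(verts[:, 0], np.arange(len(zs_vox)), zs_vox),
        ]
    )
    mesh = trimesh.Trimesh(vertices=verts_um, faces=faces, process=True)
    mesh.export(str(path), file_type="obj")
    return mesh
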