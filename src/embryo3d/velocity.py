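"""Spatial summaries of per-bead RNA velocity vectors.

Velocity vectors are estimated upstream (from spliced/unspliced ratios) and
consumed here as per-bead 2D vectors in physical space.  Three summaries:
a grid-averaged field for display (mean vector of the k beads nearest each
50 x 50 µm grid-cell center), a per-bead velocity *length* (mean speed of
the bead's k nearest neighbours, self excluded) and a per-bead directional
*confidence* (mean — or raw sum — of the cosine between the bead's vector
and its neighbours').  Low-length beads cluster into spatially connected
low-velocity regions, which in the embryo mark progenitor fields and
boundary domains.

kNN ties are broken toward the smaller bead index; distances are Euclidean
in µm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VelocityField",
    "grid_velocity",
    "velocity_length",
    "velocity_confidence",
    "low_velocity_regions",
]


@dataclass
class VelocityField:
    coords: np.ndarray    # (n, 2) µm
    vectors: np.ndarray   # (n, 2)
    k: int = 50
    pitch: float = 50.0   # µm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.coords.shape != self.vectors.shape or self.coords.shape[1] != 2:
            raise ValueError("coords and vectors must both be (n, 2)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("velocity vectors must be finite")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")

    @property
    def n_beads(self) -> int:
        return len(self.coords)


def _knn_indices(targets: np.ndarray, beads: np.ndarray, k: int,
                 exclude_self_of: np.ndarray | None = None) -> np.ndarray:
    """Indices of the k nearest beads to each target (stable tie-break by
    bead index).  ``exclude_self_of[i]`` names a bead index to drop for
    target i (self-exclusion)."""
    out = np.empty((len(targets), k), dtype=int)
    # chunk the distance matrix to bound memory
    chunk = max(1, int(2e7 // max(len(beads), 1)))
    for start in range(0, len(targets), chunk):
        t = targets[start:start + chunk]
        d = np.sqrt(((t[:, None, :] - beads[None, :, :]) ** 2).sum(axis=2))
        if exclude_self_of is not None:
            rows = np.arange(start, start + len(t))
            d[np.arange(len(t)), exclude_self_of[rows]] = np.inf
        order = np.argsort(d, axis=1, kind="stable")
        out[start:start + len(t)] = order[:, :k]
    return out


def grid_velocity(field: VelocityField) -> pd.DataFrame:
    """Mean vector of the k beads nearest each grid-cell center.

    The grid tiles the bead bounding box at the field's pitch.  Cells whose
    center has no bead within 2 x pitch are left out.  Returns a frame with
    cell indices, center coordinates and the averaged vector.
    """
    k = field.k
    if field.n_beads < k:
        warnings.warn(f"fewer beads ({field.n_beads}) than k={k}; lowering k")
        k = field.n_beads
    x0, y0 = field.coords.min(axis=0)
    x1, y1 = field.coords.max(axis=0)
    nx = max(int(np.ceil((x1 - x0) / field.pitch)), 1)
    ny = max(int(np.ceil((y1 - y0) / field.pitch)), 1)
    cx, cy = np.meshgrid(
        x0 + (np.arange(nx) + 0.5) * field.pitch,
        y0 + (np.arange(ny) + 0.5) * field.pitch,
    )
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    idx = _knn_indices(centers, field.coords, k)
    vmean = field.vectors[idx].mean(axis=1)
    # occupancy: nearest bead within 2*pitch
    nearest = np.sqrt(((centers - field.coords[idx[:, 0]]) ** 2).sum(axis=1))
    keep = nearest <= 2 * field.pitch
    ii, jj = np.divmod(np.flatnonzero(keep), nx)
    return pd.DataFrame(
        {
            "ix": jj,
            "iy": ii,
            "x": centers[keep, 0],
            "y": centers[keep, 1],
            "vx": vmean[keep, 0],
            "vy": vmean[keep, 1],
        }
    )


def velocity_length(field: VelocityField) -> np.ndarray:
    """Mean speed (vector norm) of each bead's k nearest neighbours,
    excluding the bead itself."""
    if field.n_beads < field.k + 1:
        raise ValueError(f"need at least k+1={field.k + 1} beads")
    idx = _knn_indices(field.coords, field.coords, field.k,
                       exclude_self_of=np.arange(field.n_beads))
    speeds = np.linalg.norm(field.vectors, axis=1)
    return speeds[idx].mean(axis=1)


def velocity_confidence(field: VelocityField, normalized: bool = True) -> np.ndarray:
    """Coherence of each bead's vector with its k nearest neighbours'.

    The cosine between the bead's vector and each neighbour's is averaged
    (``normalized=True``, values in [−1, 1]) or summed (the raw variant).
    Zero-magnitude neighbour vectors are excluded with count adjustment; a
    bead whose own vector is zero gets NaN.
    """
    if field.n_beads < field.k + 1:
        raise ValueError(f"need at least k+1={field.k + 1} beads")
    idx = _knn_indices(field.coords, field.coords, field.k,
                       exclude_self_of=np.arange(field.n_beads))
    v = field.vectors
    norms = np.linalg.norm(v, axis=1)
    out = np.full(field.n_beads, np.nan)
    for i in range(field.n_beads):
        if norms[i] == 0:
            continue
        nb = idx[i]
        ok = norms[nb] > 0
        if not ok.any():
            out[i] = 0.0
            continue
        cos = (v[nb[ok]] @ v[i]) / (norms[nb[ok]] * norms[i])
        # raw variant: count-adjusted sum (mean over valid neighbours times k)
        out[i] = cos.mean() if normalized else cos.mean() * field.k
    return out


def low_velocity_regions(
    coords: np.ndarray,
    length: np.ndarray,
    confidence: np.ndarray | None = None,
    length_quantile: float = 0.2,
    min_region_beads: int = 30,
    pitch: float = 50.0,
    order_axis: tuple[float, float] = (1.0, 0.0),
) -> np.ndarray:
    """Label spatially connected groups of low-velocity beads.

    Beads with length below the ``length_quantile`` quantile are flagged
    (optionally restricted to beads whose confidence is available), grouped
    into connected components of the neighbour graph at radius 2 x pitch,
    and components with at least ``min_region_beads`` beads are labelled
    "R1", "R2", ... ordered by component centroid along ``order_axis``.
    Unlabelled beads get "".
    """
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial import cKDTree

    coords = np.asarray(coords, dtype=float)
    length = np.asarray(length, dtype=float)
    thr = np.quantile(length, length_quantile)
    low = length < thr  # strict: a constant-speed field flags nothing
    if confidence is not None:
        low &= np.isfinite(np.asarray(confidence, dtype=float))
    flagged = np.flatnonzero(low)
    labels = np.full(len(coords), "", dtype=object)
    if flagged.size == 0:
        return labels
    tree = cKDTree(coords[flagged])
    pairs = tree.sparse_distance_matrix(tree, max_distance=2 * pitch, output_type="coo_matrix")
    n_comp, comp = connected_components(pairs.tocsr(), directed=False)
    u = np.asarray(order_axis, dtype=float)
    regions = []
    for c in range(n_comp):
        members = flagged[comp == c]
        if len(members) >= min_region_beads:
            regions.append((float(coords[members].mean(axis=0) @ u), members))
    regions.sort(key=lambda t: t[0])
    for r, (_, members) in enumerate(regions, start=1):
        labels[members] = f"R{r}"
    return labels
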