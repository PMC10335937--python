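"""Virtual in situ hybridization: querying expression in the 3D embryo.

Once a stack is registered, any gene can be rendered as a 3D point cloud of
normalized expression (``query_gene``), two genes can be overlaid and
classified per bead (``dual_gene``), and expression can be profiled along an
arbitrary body axis (``axis_profile``) — the axis given by an origin, a
direction, and two Euler-style angles (rotation = azimuthal spin of the
frame about the axis, inclination = tilt of the axis about the spun normal)
that let the profile plane family be tipped the way a sectioning plane would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import EmbryoStack, normalize

__all__ = ["AxisSpec", "ExpressionProfile", "query_gene", "dual_gene", "axis_profile"]


class GeneLookupError(KeyError):
    pass


@dataclass(frozen=True)
class AxisSpec:
    """A 1D profiling axis through the reconstructed embryo.

    ``direction`` need not be normalized (it will be).  ``rotation`` spins an
    orthonormal frame (e1, e2) about the axis; ``inclination`` then tilts the
    axis about the spun e1.  ``extent`` is (lo, hi) µm along the axis or None
    for the data range.
    """

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    inclination: float = 0.0
    rotation: float = 0.0
    n_bins: int = 25
    extent: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if np.linalg.norm(self.direction) == 0:
            raise ValueError("direction must be nonzero")

    def effective_direction(self) -> np.ndarray:
        """Unit projection axis after applying rotation and inclination."""
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        # build a frame (d, e1, e2)
        helper = np.array([0.0, 0.0, 1.0])
        if abs(d @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, helper)
        e1 /= np.linalg.norm(e1)
        e1 = _rotate_about(e1, d, self.rotation)
        return _rotate_about(d, e1, self.inclination)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Signed coordinate s (µm) of each point along the effective axis."""
        u = self.effective_direction()
        return (np.asarray(points, dtype=float) - np.asarray(self.origin)) @ u


def _rotate_about(v: np.ndarray, axis: np.ndarray, degrees: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    t = np.deg2rad(degrees)
    axis = axis / np.linalg.norm(axis)
    return (
        v * np.cos(t)
        + np.cross(axis, v) * np.sin(t)
        + axis * (axis @ v) * (1 - np.cos(t))
    )


@dataclass
class ExpressionProfile:
    """Binned mean expression along a 1D coordinate."""

    bin_edges: np.ndarray       # (n_bins + 1,) µm; bins half-open, last closed
    mean: np.ndarray            # per-bin mean normalized expression (NaN if empty)
    count: np.ndarray           # per-bin bead count
    se: np.ndarray              # per-bin standard error (NaN where undefined)

    @property
    def n_bins(self) -> int:
        return len(self.count)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "mean": self.mean,
                "count": self.count,
                "se": self.se,
            }
        )


def _gene_column(stack: EmbryoStack, gene: str) -> int:
    names = stack.gene_names
    try:
        return int(names.get_loc(gene))
    except KeyError:
        near = [n for n in names if gene.lower() in n.lower() or n.lower() in gene.lower()]
        raise GeneLookupError(
            f"gene {gene!r} not in stack" + (f"; near matches: {near[:5]}" if near else "")
        ) from None


def query_gene(
    stack: EmbryoStack,
    gene: str,
    tissue: str | None = None,
    target_sum: float = 1e4,
    log1p: bool = True,
) -> pd.DataFrame:
    """Per-bead normalized expression of one gene with registered 3D coordinates.

    Returns a frame with x, y, z, cell_state and ``value`` columns, optionally
    restricted to one tissue (cell-state label).
    """
    col = _gene_column(stack, gene)
    beads = stack.beads_3d()
    counts = stack.counts_matrix()
    norm = normalize(counts, target_sum=target_sum, log1p=log1p)
    beads = beads.assign(value=norm[:, col])
    if tissue is not None:
        beads = beads[beads["cell_state"] == tissue].reset_index(drop=True)
    return beads


def dual_gene(
    stack: EmbryoStack,
    geneA: str,
    geneB: str,
    thrA: float = 0.0,
    thrB: float = 0.0,
    tissue: str | None = None,
    target_sum: float = 1e4,
    log1p: bool = True,
) -> pd.DataFrame:
    """Classify each bead as 'A only', 'B only', 'both' or 'neither'.

    A bead expresses a gene when its normalized expression exceeds the gene's
    threshold (strictly).  The four classes partition the bead set.
    """
    if thrA < 0 or thrB < 0:
        raise ValueError("thresholds must be >= 0")
    a = query_gene(stack, geneA, tissue, target_sum, log1p)
    b = query_gene(stack, geneB, tissue, target_sum, log1p)
    exprA = a["value"].to_numpy() > thrA
    exprB = b["value"].to_numpy() > thrB
    cls = np.where(
        exprA & exprB, "both",
        np.where(exprA, "A only", np.where(exprB, "B only", "neither")),
    )
    out = a.rename(columns={"value": "valueA"})
    out["valueB"] = b["value"].to_numpy()
    out["class"] = cls
    return out


def axis_profile(
    stack: EmbryoStack,
    gene: str,
    axis: AxisSpec,
    tissue: str | None = None,
    target_sum: float = 1e4,
    log1p: bool = True,
) -> ExpressionProfile:
    """Mean expression in equal-width bins along an arbitrary axis.

    Beads are projected onto the axis; those inside the extent are binned
    into ``axis.n_bins`` half-open equal-width bins (last bin closed).  Empty
    bins report count 0 and NaN mean/se.
    """
    beads = query_gene(stack, gene, tissue, target_sum, log1p)
    pts = beads[["x", "y", "z"]].to_numpy()
    s = axis.project(pts)
    lo, hi = axis.extent if axis.extent is not None else (float(s.min()), float(s.max()))
    if hi <= lo:
        raise ValueError("axis extent must have positive length")
    inside = (s >= lo) & (s <= hi)
    if not inside.any():
        raise ValueError("no bead within the axis extent")
    s_in = s[inside]
    v_in = beads["value"].to_numpy()[inside]
    edges = np.linspace(lo, hi, axis.n_bins + 1)
    idx = np.minimum(((s_in - lo) / (hi - lo) * axis.n_bins).astype(int), axis.n_bins - 1)
    count = np.bincount(idx, minlength=axis.n_bins).astype(int)
    sums = np.bincount(idx, weights=v_in, minlength=axis.n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, sums / np.maximum(count, 1), np.nan)
        sq = np.bincount(idx, weights=v_in**2, minlength=axis.n_bins)
        var = np.where(count > 1, (sq - count * mean**2) / np.maximum(count - 1, 1), np.nan)
        se = np.sqrt(np.clip(var, 0, None) / np.maximum(count, 1))
        se = np.where(count > 1, se, np.nan)
    return ExpressionProfile(bin_edges=edges, mean=mean, count=count, se=se)
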