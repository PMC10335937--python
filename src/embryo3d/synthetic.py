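"""Seeded synthetic embryos with known ground truth.

The generator builds a 3D "embryo" out of ellipsoidal tissues, plants gene
expression programs on it (uniform, axial gradient, focal spot, staggered
Hox-like bumps) with negative-binomial count noise, cuts it into serial
sections with unknown per-section rigid perturbations, and plants velocity
and pseudotime fields.  Every quantity the analysis modules estimate —
transforms, volumes, pattern parameters — is available as ground truth, so
recovery can be measured exactly.

The NB noise model is mean/dispersion parameterized: variance = mu + alpha*mu^2,
matching the count model assumed by the trend test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_model import EmbryoStack, SpatialArray
from .transforms import RigidTransform2D

__all__ = [
    "Ellipsoid",
    "PatternSpec",
    "TissueSpec",
    "EmbryoSpec",
    "GroundTruth",
    "generate_embryo",
    "slice_embryo",
    "plant_velocity",
    "default_embryo_spec",
]


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]  # µm
    semi_axes: tuple[float, float, float]  # µm

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def contains(self, points: np.ndarray) -> np.ndarray:
        q = (np.asarray(points) - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (q**2).sum(axis=1) <= 1.0


@dataclass(frozen=True)
class PatternSpec:
    """Expression program for one gene.

    pattern kinds and their params:
      uniform                  — constant mean ``base_mean``
      linear_gradient          — mean = base_mean * 2**(slope * s), s = centered
                                 projection (µm) on ``axis``; slope in
                                 doublings per µm
      focal                    — Gaussian bump at ``center`` with sd ``sd`` µm
      module_bump              — Gaussian bump at arclength ``position`` µm
                                 along ``axis`` with sd ``width`` µm
    """

    gene: str
    pattern: str = "uniform"
    tissue_scope: str = "all"
    base_mean: float = 5.0
    dispersion: float = 0.1
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    slope: float = 0.0  # doublings per µm (linear_gradient)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)  # focal
    sd: float = 50.0  # focal
    position: float = 0.0  # module_bump, µm along axis
    width: float = 50.0  # module_bump

    def __post_init__(self) -> None:
        if self.base_mean <= 0:
            raise ValueError("base_mean must be > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.pattern not in {"uniform", "linear_gradient", "focal", "module_bump"}:
            raise ValueError(f"unknown pattern {self.pattern!r}")

    def mean_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        if self.pattern == "uniform":
            return np.full(len(pts), self.base_mean)
        if self.pattern == "linear_gradient":
            u = np.asarray(self.axis, dtype=float)
            u = u / np.linalg.norm(u)
            s = pts @ u
            s = s - s.mean()
            return self.base_mean * np.exp2(self.slope * s)
        if self.pattern == "focal":
            d2 = ((pts - np.asarray(self.center)) ** 2).sum(axis=1)
            return self.base_mean * np.exp(-d2 / (2 * self.sd**2))
        # module_bump
        u = np.asarray(self.axis, dtype=float)
        u = u / np.linalg.norm(u)
        s = pts @ u
        s = s - s.min()
        return self.base_mean * np.exp(-((s - self.position) ** 2) / (2 * self.width**2))


@dataclass(frozen=True)
class TissueSpec:
    name: str
    shape: Ellipsoid
    bead_density: float = 1.0  # beads per 10^3 µm^3

    def __post_init__(self) -> None:
        if self.bead_density <= 0:
            raise ValueError("bead density must be positive")


@dataclass(frozen=True)
class EmbryoSpec:
    tissues: tuple[TissueSpec, ...]
    genes: tuple[PatternSpec, ...]
    seed: int = 0


@dataclass
class GroundTruth:
    """A generated embryo with everything the pipeline is asked to recover."""

    positions: np.ndarray          # (n_beads, 3) µm
    tissue: np.ndarray             # (n_beads,) tissue names
    counts: sp.csr_matrix          # (n_beads, n_genes)
    gene_names: pd.Index
    spec: EmbryoSpec
    pseudotime: np.ndarray | None = None
    velocity: np.ndarray | None = None          # (n_beads, 2), in-plane (x, y)
    true_transforms: list[RigidTransform2D] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


def _sample_ellipsoid(rng: np.random.Generator, ell: Ellipsoid, n: int) -> np.ndarray:
    """Uniform points inside an ellipsoid (unit-ball sampling, then scaling)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None] * np.asarray(ell.semi_axes) + np.asarray(ell.center)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with variance mu + alpha*mu^2 (gamma-Poisson mixture)."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-12, None)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def generate_embryo(spec: EmbryoSpec) -> GroundTruth:
    """Sample beads in each tissue and draw planted NB counts.

    Beads land uniformly inside each ellipsoid at the stated density (Poisson
    number of beads).  Beads falling inside several tissues belong to the
    first-listed one (with a warning).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    positions, labels = [], []
    for i, tissue in enumerate(spec.tissues):
        n = rng.poisson(tissue.bead_density * tissue.shape.volume / 1e3)
        pts = _sample_ellipsoid(rng, tissue.shape, n)
        if i > 0:
            inside_earlier = np.zeros(len(pts), dtype=bool)
            for prev in spec.tissues[:i]:
                inside_earlier |= prev.shape.contains(pts)
            if inside_earlier.any():
                warnings.warn(
                    f"{inside_earlier.sum()} beads of tissue {tissue.name!r} overlap an "
                    "earlier-listed tissue and are assigned to it"
                )
                labels_prev = np.empty(inside_earlier.sum(), dtype=object)
                # assign to the first earlier tissue that contains them
                sub = pts[inside_earlier]
                labels_prev[:] = tissue.name
                for prev in spec.tissues[:i]:
                    hit = prev.shape.contains(sub) & (labels_prev == tissue.name)
                    labels_prev[hit] = prev.name
                lab = np.empty(len(pts), dtype=object)
                lab[:] = tissue.name
                lab[inside_earlier] = labels_prev
                positions.append(pts)
                labels.append(lab)
                continue
        positions.append(pts)
        lab = np.empty(len(pts), dtype=object)
        lab[:] = tissue.name
        labels.append(lab)
    pos = np.concatenate(positions) if positions else np.empty((0, 3))
    tissue_labels = np.concatenate(labels) if labels else np.empty(0, dtype=object)

    cols = []
    for gene in spec.genes:
        mean = gene.mean_at(pos)
        if gene.tissue_scope != "all":
            mean = np.where(tissue_labels == gene.tissue_scope, mean, 0.0)
        cols.append(_nb_sample(rng, mean, gene.dispersion))
    counts = sp.csr_matrix(np.column_stack(cols)) if cols else sp.csr_matrix((len(pos), 0))

    # pseudotime: normalized head-to-tail (x-axis) position — a simple proxy
    # for a differentiation axis the distance analyses can be tested against
    if len(pos):
        x = pos[:, 0]
        ptime = (x - x.min()) / max(x.max() - x.min(), 1e-12)
    else:
        ptime = np.empty(0)

    return GroundTruth(
        positions=pos,
        tissue=tissue_labels,
        counts=counts,
        gene_names=pd.Index([g.gene for g in spec.genes]),
        spec=spec,
        pseudotime=ptime,
    )


def slice_embryo(
    truth: GroundTruth,
    thickness: float = 10.0,
    gap: float = 30.0,
    max_rot: float = 20.0,
    max_trans: float = 100.0,
    flip_prob: float = 0.0,
    seed: int = 0,
) -> tuple[EmbryoStack, list[RigidTransform2D]]:
    """Cut the embryo into sections along z and perturb each one.

    Slice k collects beads with z in [z_min + k*(thickness+gap),
    z_min + k*(thickness+gap) + thickness); beads falling in gaps are dropped.
    Each slice is independently perturbed by a rigid transform with rotation
    uniform in ±max_rot, translation uniform in ±max_trans per component and a
    Bernoulli(flip_prob) mirror; the applied transforms are returned as ground
    truth (their inverses restore the original in-plane coordinates).
    """
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    if gap < 0:
        raise ValueError("gap must be >= 0")
    rng = np.random.default_rng(seed)
    z = truth.positions[:, 2]
    z_min, z_max = z.min(), z.max()
    period = thickness + gap
    n_slices = int(np.ceil((z_max - z_min) / period)) if z_max > z_min else 1
    if n_slices <= 1 and period > (z_max - z_min):
        if period > (z_max - z_min) and gap > 0 and n_slices <= 1:
            warnings.warn("slab period exceeds embryo extent; single-slice stack")
        n_slices = max(n_slices, 1)

    arrays, transforms = [], []
    for k in range(n_slices):
        lo = z_min + k * period
        sel = np.flatnonzero((z >= lo) & (z < lo + thickness))
        if k == n_slices - 1:  # include beads exactly at the top boundary
            sel = np.flatnonzero(((z >= lo) & (z < lo + thickness)) | (z == z_max))
            sel = np.unique(sel)
        if sel.size == 0:
            continue
        xy = truth.positions[sel, :2]
        theta = rng.uniform(-max_rot, max_rot)
        tx, ty = rng.uniform(-max_trans, max_trans, size=2)
        flip = bool(rng.random() < flip_prob)
        t = RigidTransform2D(
            theta=theta, tx=tx, ty=ty, flip=flip, pivot=tuple(xy.mean(axis=0))
        )
        arrays.append(
            SpatialArray(
                array_id=f"slice_{k:02d}",
                coords=t.apply(xy),
                counts=truth.counts[sel],
                gene_names=truth.gene_names,
                bead_ids=pd.Index([f"b{j}" for j in sel]),
                cell_state=truth.tissue[sel],
                prediction_score=np.ones(sel.size),
                z_index=k,
                thickness=thickness,
                gap_to_next=gap,
            )
        )
        transforms.append(t)
    if not arrays:
        raise ValueError("no beads fell into any slab")
    stack = EmbryoStack(arrays=arrays, reference_index=len(arrays) // 2)
    truth.true_transforms = transforms
    return stack, transforms


def plant_velocity(
    truth: GroundTruth,
    field: str = "uniform",
    vector: tuple[float, float] = (1.0, 0.0),
    center: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    magnitude: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Assign in-plane (x, y) velocity vectors by a simple field formula.

    ``uniform``: every bead gets ``vector``.  ``rotational``: solid-body
    rotation about ``center`` (divergence-free).  ``convergent``: unit vectors
    pointing at the sink ``center`` scaled by ``magnitude`` times the
    normalized distance (so speed shrinks toward the sink).  Seeded isotropic
    Gaussian noise of sd ``noise_sd`` is added.
    """
    rng = np.random.default_rng(seed)
    xy = truth.positions[:, :2]
    if field == "uniform":
        v = np.tile(np.asarray(vector, dtype=float), (len(xy), 1))
    elif field == "rotational":
        d = xy - np.asarray(center)
        v = magnitude * np.column_stack([-d[:, 1], d[:, 0]]) / max(
            np.abs(d).max(), 1e-12
        )
    elif field == "convergent":
        d = np.asarray(center) - xy
        dist = np.linalg.norm(d, axis=1)
        unit = d / np.maximum(dist[:, None], 1e-12)
        v = magnitude * unit * (dist / max(dist.max(), 1e-12))[:, None]
    else:
        raise ValueError(f"unknown field {field!r}")
    if noise_sd > 0:
        v = v + rng.normal(scale=noise_sd, size=v.shape)
    truth.velocity = v
    return v


def default_embryo_spec(
    seed: int = 0,
    n_uniform: int = 0,
    n_focal: int = 0,
    extra_genes: tuple[PatternSpec, ...] = (),
) -> EmbryoSpec:
    """A three-tissue cartoon embryo in the size regime of early mouse
    organogenesis: an elongated central trunk, a thinner neural tube dorsal to
    it and a heart tube ventral and anterior, all spanning ~600 µm of z so
    that every sagittal section carries an asymmetric multi-tissue layout
    (like real sections, where the arrangement of cell states orients the
    slice).  Bead density 1 per 10^3 µm^3, i.e. the 10-µm bead pitch scale.
    """
    tissues = (
        TissueSpec("trunk", Ellipsoid((0.0, 0.0, 0.0), (420.0, 180.0, 300.0)), 1.0),
        TissueSpec("neural_tube", Ellipsoid((-40.0, 270.0, 0.0), (380.0, 70.0, 300.0)), 1.0),
        TissueSpec("heart", Ellipsoid((180.0, -290.0, 0.0), (150.0, 95.0, 300.0)), 1.2),
    )
    rng = np.random.default_rng(seed)
    genes = list(extra_genes)
    for i in range(n_uniform):
        genes.append(PatternSpec(gene=f"unif{i}", pattern="uniform", base_mean=5.0))
    for i in range(n_focal):
        # focal spots scattered through the trunk
        c = (float(rng.uniform(-300, 300)), float(rng.uniform(-120, 120)),
             float(rng.uniform(-180, 180)))
        genes.append(
            PatternSpec(gene=f"focal{i}", pattern="focal", base_mean=20.0, center=c, sd=60.0)
        )
    return EmbryoSpec(tissues=tissues, genes=tuple(genes), seed=seed)
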