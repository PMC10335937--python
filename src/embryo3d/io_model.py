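"""Containers and I/O for spot-based spatial transcriptomic sections.

A :class:`SpatialArray` is one 2D section: bead coordinates in µm, a
bead x gene count matrix, per-bead cell-state labels with label-transfer
prediction scores, and the section's position in the cutting series
(z index, thickness, gap to the next section).  A :class:`EmbryoStack` is the
ordered series together with one rigid transform per section — the "virtual
embryo" once the transforms have been estimated.

File formats: an h5ad dialect (via :mod:`anndata`) or CSV coordinates +
MatrixMarket counts + a gene list.  All counts are raw non-negative integers;
normalization is explicit and separate (:func:`normalize`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .transforms import RigidTransform2D

__all__ = [
    "SpatialArray",
    "EmbryoStack",
    "read_array",
    "qc_filter",
    "normalize",
    "write_stack",
    "read_stack",
]


class FormatError(ValueError):
    """The input file is missing required fields or is not parseable."""


class ValidationError(ValueError):
    """The parsed data violates a container invariant."""


def _dedup_gene_names(names: list[str]) -> list[str]:
    """Deterministically deduplicate: repeats get '.1', '.2', ... suffixes."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


@dataclass
class SpatialArray:
    """One 2D spatial transcriptomic section.

    Coordinates are µm with y increasing upward; beads are points (the 10-µm
    bead pitch is metadata, not geometry).  ``counts`` is beads x genes,
    raw integers.
    """

    array_id: str
    coords: np.ndarray            # (n_beads, 2) µm
    counts: sp.csr_matrix        # (n_beads, n_genes) non-negative ints
    gene_names: pd.Index
    bead_ids: pd.Index
    cell_state: np.ndarray        # (n_beads,) str labels
    prediction_score: np.ndarray  # (n_beads,) in [0, 1]
    z_index: int = 0
    thickness: float = 10.0
    gap_to_next: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be (n_beads, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("bead coordinates must be finite")
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape[0] != self.coords.shape[0]:
            raise ValidationError(
                f"counts has {self.counts.shape[0]} beads but coords has "
                f"{self.coords.shape[0]}"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValidationError("counts must be non-negative integers")
        self.gene_names = pd.Index(self.gene_names)
        if self.counts.shape[1] != len(self.gene_names):
            raise ValidationError("gene_names length must match counts columns")
        if not self.gene_names.is_unique:
            raise ValidationError("gene_names must be unique (deduplicate on read)")
        self.bead_ids = pd.Index(self.bead_ids)
        self.cell_state = np.asarray(self.cell_state, dtype=object)
        self.prediction_score = np.asarray(self.prediction_score, dtype=float)

    # -- derived per-bead QC quantities -----------------------------------

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def mito_fraction(self, mito_prefix: str = "mt-") -> np.ndarray:
        """Fraction of counts on mitochondrial genes (case-insensitive prefix)."""
        is_mito = self.gene_names.str.lower().str.startswith(mito_prefix.lower())
        mito = np.asarray(self.counts[:, np.asarray(is_mito)].sum(axis=1)).ravel()
        total = self.total_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
        return frac

    def subset(self, mask: np.ndarray) -> "SpatialArray":
        """New array keeping beads where mask is True, order preserved."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            coords=self.coords[idx],
            counts=self.counts[idx],
            bead_ids=self.bead_ids[idx],
            cell_state=self.cell_state[idx],
            prediction_score=self.prediction_score[idx],
        )

    def subset_genes(self, genes: pd.Index) -> "SpatialArray":
        idx = self.gene_names.get_indexer(genes)
        if np.any(idx < 0):
            raise KeyError("genes not present in array")
        return replace(self, counts=self.counts[:, idx], gene_names=pd.Index(genes))

    # -- anndata bridge ----------------------------------------------------

    def to_anndata(self) -> ad.AnnData:
        obs = pd.DataFrame(
            {
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "cell_state": pd.Series(self.cell_state, dtype=str).values,
                "prediction_score": self.prediction_score,
            },
            index=self.bead_ids.astype(str),
        )
        adata = ad.AnnData(
            X=self.counts.copy(), obs=obs, var=pd.DataFrame(index=self.gene_names)
        )
        adata.uns["array_id"] = self.array_id
        adata.uns["z_index"] = int(self.z_index)
        adata.uns["thickness"] = float(self.thickness)
        adata.uns["gap_to_next"] = float(self.gap_to_next)
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, array_id: str | None = None) -> "SpatialArray":
        for col in ("x", "y"):
            if col not in adata.obs:
                raise FormatError(f"missing coordinate field '{col}' in obs")
        X = adata.X
        counts = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
        return cls(
            array_id=array_id or str(adata.uns.get("array_id", "array")),
            coords=np.column_stack([adata.obs["x"].to_numpy(), adata.obs["y"].to_numpy()]),
            counts=counts,
            gene_names=pd.Index(_dedup_gene_names(list(adata.var_names))),
            bead_ids=pd.Index(adata.obs_names),
            cell_state=adata.obs.get(
                "cell_state", pd.Series("unknown", index=adata.obs_names)
            ).to_numpy(),
            prediction_score=adata.obs.get(
                "prediction_score", pd.Series(1.0, index=adata.obs_names)
            ).to_numpy(dtype=float),
            z_index=int(adata.uns.get("z_index", 0)),
            thickness=float(adata.uns.get("thickness", 10.0)),
            gap_to_next=float(adata.uns.get("gap_to_next", 0.0)),
        )


# ---------------------------------------------------------------------------
# file I/O


def read_array(path: str | Path, dialect: str = "h5ad", **kwargs) -> SpatialArray:
    """Read one section from disk.

    ``dialect='h5ad'`` expects an AnnData file (X = raw counts; obs holds x, y,
    cell_state, prediction_score; uns holds z_index/thickness/gap_to_next).
    ``dialect='csv+mtx'`` expects *path* to be the coordinates CSV
    (bead_id,x,y[,cell_state,prediction_score]) with the counts as
    MatrixMarket next to it (keyword ``mtx``, genes x beads) and a gene list
    text file (keyword ``genes``, one name per line).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "h5ad":
        return SpatialArray.from_anndata(ad.read_h5ad(path))
    if dialect == "csv+mtx":
        from scipy.io import mmread

        mtx_path = Path(kwargs.get("mtx", path.with_suffix(".mtx")))
        genes_path = Path(kwargs.get("genes", path.with_name(path.stem + "_genes.txt")))
        coords = pd.read_csv(path)
        for col in ("bead_id", "x", "y"):
            if col not in coords.columns:
                raise FormatError(f"coordinates CSV missing column '{col}'")
        mat = mmread(mtx_path)  # genes x beads on disk
        counts = sp.csr_matrix(mat.T)
        if np.any(counts.data < 0) or np.any(counts.data != np.round(counts.data)):
            raise ValidationError("counts must be non-negative integers")
        gene_names = _dedup_gene_names(genes_path.read_text().split())
        return SpatialArray(
            array_id=kwargs.get("array_id", path.stem),
            coords=coords[["x", "y"]].to_numpy(float),
            counts=counts,
            gene_names=pd.Index(gene_names),
            bead_ids=pd.Index(coords["bead_id"].astype(str)),
            cell_state=coords.get("cell_state", pd.Series(["unknown"] * len(coords))).to_numpy(),
            prediction_score=coords.get(
                "prediction_score", pd.Series(1.0, index=coords.index)
            ).to_numpy(dtype=float),
            z_index=int(kwargs.get("z_index", 0)),
            thickness=float(kwargs.get("thickness", 10.0)),
            gap_to_next=float(kwargs.get("gap_to_next", 0.0)),
        )
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# QC and normalization


def qc_filter(
    array: SpatialArray,
    min_counts: int = 200,
    max_mito: float = 0.20,
    min_prediction: float = 0.0,
    mito_prefix: str = "mt-",
) -> SpatialArray:
    """Retain beads with total counts strictly above ``min_counts``, mito
    fraction strictly below ``max_mito`` and prediction score at least
    ``min_prediction`` (beads scoring lower are discarded).  Order preserved;
    idempotent.
    """
    for name, val in (("min_counts", min_counts), ("max_mito", max_mito),
                      ("min_prediction", min_prediction)):
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite")
    keep = (
        (array.total_counts > min_counts)
        & (array.mito_fraction(mito_prefix) < max_mito)
        & (array.prediction_score >= min_prediction)
    )
    if not keep.any():
        warnings.warn(f"QC removed every bead of array {array.array_id!r}")
    return array.subset(keep)


def normalize(
    array: SpatialArray | sp.spmatrix | np.ndarray,
    target_sum: float = 1e4,
    log1p: bool = True,
) -> np.ndarray:
    """Library-size normalize a beads x genes count matrix.

    Each bead with nonzero counts is scaled so its counts sum to
    ``target_sum``, then optionally log1p-transformed.  Zero-count beads map
    to all-zero rows.  Returns a dense (beads x genes) float array.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be > 0")
    counts = array.counts if isinstance(array, SpatialArray) else array
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    totals = dense.sum(axis=1)
    scale = np.where(totals > 0, target_sum / np.maximum(totals, 1e-300), 0.0)
    out = dense * scale[:, None]
    return np.log1p(out) if log1p else out


# ---------------------------------------------------------------------------
# stacks


@dataclass
class EmbryoStack:
    """An ordered series of sections with per-section rigid transforms.

    ``z_positions`` are slice-center z in µm, derived from cumulative
    thickness + gap; ``transforms[reference_index]`` is the identity and every
    other transform maps that section's local coordinates into the reference
    frame.  Gene panels are harmonized to the intersection at assembly.
    """

    arrays: list[SpatialArray]
    transforms: list[RigidTransform2D] = field(default_factory=list)
    reference_index: int | None = None

    def __post_init__(self) -> None:
        if not self.arrays:
            raise ValidationError("a stack needs at least one array")
        genes = self.arrays[0].gene_names
        for arr in self.arrays[1:]:
            genes = genes.intersection(arr.gene_names)
        if len(genes) == 0 and all(a.n_genes > 0 for a in self.arrays):
            raise ValidationError("gene panels have empty intersection")
        genes = self.arrays[0].gene_names[self.arrays[0].gene_names.isin(genes)]
        self.arrays = [
            a if a.gene_names.equals(genes) else a.subset_genes(genes) for a in self.arrays
        ]
        if self.reference_index is None:
            self.reference_index = len(self.arrays) // 2
        if not self.transforms:
            self.transforms = [RigidTransform2D.identity() for _ in self.arrays]
        if len(self.transforms) != len(self.arrays):
            raise ValidationError("one transform per array required")
        if not self.transforms[self.reference_index].is_identity:
            raise ValidationError("transform at the reference index must be identity")
        z = self.z_positions
        if len(z) > 1 and not np.all(np.diff(z) > 0):
            raise ValidationError("z positions must be strictly increasing")

    @property
    def n_slices(self) -> int:
        return len(self.arrays)

    @property
    def gene_names(self) -> pd.Index:
        return self.arrays[0].gene_names

    @property
    def z_positions(self) -> np.ndarray:
        """Slice-center z: slice i sits at start_i + thickness/2."""
        starts = np.concatenate(
            [[0.0], np.cumsum([a.thickness + a.gap_to_next for a in self.arrays[:-1]])]
        )
        return starts + np.array([a.thickness / 2 for a in self.arrays])

    def registered_coords(self, index: int) -> np.ndarray:
        """Section *index*'s bead coordinates in the reference frame (µm)."""
        return self.transforms[index].apply(self.arrays[index].coords)

    def beads_3d(self) -> pd.DataFrame:
        """All beads in the reference frame: x, y, z, array, state, bead id."""
        frames = []
        for i, (arr, z) in enumerate(zip(self.arrays, self.z_positions)):
            xy = self.registered_coords(i)
            frames.append(
                pd.DataFrame(
                    {
                        "x": xy[:, 0],
                        "y": xy[:, 1],
                        "z": z,
                        "array_index": i,
                        "array_id": arr.array_id,
                        "bead_id": arr.bead_ids,
                        "cell_state": arr.cell_state,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def counts_matrix(self) -> sp.csr_matrix:
        """Counts for all beads (rows follow :meth:`beads_3d` order)."""
        return sp.vstack([a.counts for a in self.arrays]).tocsr()

    def with_transforms(self, transforms: list[RigidTransform2D]) -> "EmbryoStack":
        return EmbryoStack(
            arrays=list(self.arrays),
            transforms=list(transforms),
            reference_index=self.reference_index,
        )


def write_stack(stack: EmbryoStack, path: str | Path) -> None:
    """Write a stack as one h5ad file (lossless round-trip)."""
    path = Path(path)
    obs_frames, counts = [], []
    for i, arr in enumerate(stack.arrays):
        obs_frames.append(
            pd.DataFrame(
                {
                    "x": arr.coords[:, 0],
                    "y": arr.coords[:, 1],
                    "cell_state": pd.Series(arr.cell_state, dtype=str).values,
                    "prediction_score": arr.prediction_score,
                    "array_index": i,
                    "bead_id": arr.bead_ids.astype(str),
                },
                index=[f"{i}:{b}" for b in arr.bead_ids],
            )
        )
        counts.append(arr.counts)
    adata = ad.AnnData(
        X=sp.vstack(counts).tocsr(),
        obs=pd.concat(obs_frames),
        var=pd.DataFrame(index=stack.gene_names),
    )
    adata.uns["array_ids"] = [a.array_id for a in stack.arrays]
    adata.uns["z_index"] = [int(a.z_index) for a in stack.arrays]
    adata.uns["thickness"] = [float(a.thickness) for a in stack.arrays]
    adata.uns["gap_to_next"] = [float(a.gap_to_next) for a in stack.arrays]
    adata.uns["reference_index"] = int(stack.reference_index)
    adata.uns["transforms"] = np.array(
        [[t.theta, t.tx, t.ty, float(t.flip), t.pivot[0], t.pivot[1]] for t in stack.transforms]
    )
    adata.write_h5ad(path)


def read_stack(path: str | Path) -> EmbryoStack:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        adata = ad.read_h5ad(path)
    except Exception as exc:  # corrupted container
        raise FormatError(f"cannot read stack container {path}: {exc}") from exc
    if "transforms" not in adata.uns or "array_ids" not in adata.uns:
        raise FormatError("file is not an embryo3d stack (missing uns metadata)")
    arrays, transforms = [], []
    for i, array_id in enumerate(adata.uns["array_ids"]):
        m = np.asarray(adata.obs["array_index"] == i)
        sub = adata[m]
        arrays.append(
            SpatialArray(
                array_id=str(array_id),
                coords=np.column_stack(
                    [sub.obs["x"].to_numpy(), sub.obs["y"].to_numpy()]
                ),
                counts=sp.csr_matrix(sub.X),
                gene_names=pd.Index(adata.var_names),
                bead_ids=pd.Index(sub.obs["bead_id"].astype(str)),
                cell_state=sub.obs["cell_state"].to_numpy(),
                prediction_score=sub.obs["prediction_score"].to_numpy(dtype=float),
                z_index=int(adata.uns["z_index"][i]),
                thickness=float(adata.uns["thickness"][i]),
                gap_to_next=float(adata.uns["gap_to_next"][i]),
            )
        )
        row = adata.uns["transforms"][i]
        transforms.append(
            RigidTransform2D(
                theta=float(row[0]),
                tx=float(row[1]),
                ty=float(row[2]),
                flip=bool(row[3]),
                pivot=(float(row[4]), float(row[5])),
            )
        )
    return EmbryoStack(
        arrays=arrays,
        transforms=transforms,
        reference_index=int(adata.uns["reference_index"]),
    )
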