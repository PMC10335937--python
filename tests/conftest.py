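import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from embryo3d.io_model import SpatialArray
from embryo3d.synthetic import (
    Ellipsoid,
    EmbryoSpec,
    PatternSpec,
    TissueSpec,
    generate_embryo,
    slice_embryo,
)


def make_array(coords, counts, gene_names=None, cell_state=None, scores=None, **kw):
    """Hand-rolled SpatialArray for small fixtures."""
    coords = np.asarray(coords, dtype=float)
    counts = np.asarray(counts)
    n = len(coords)
    return SpatialArray(
        array_id=kw.pop("array_id", "test"),
        coords=coords,
        counts=sp.csr_matrix(counts),
        gene_names=pd.Index(gene_names or [f"g{i}" for i in range(counts.shape[1])]),
        bead_ids=pd.Index([f"b{i}" for i in range(n)]),
        cell_state=np.asarray(cell_state if cell_state is not None else ["t"] * n),
        prediction_score=np.asarray(scores if scores is not None else np.ones(n)),
        **kw,
    )


@pytest.fixture(scope="session")
def sphere_stack():
    """Sphere of radius 100 µm cut into contiguous 10-µm sections."""
    spec = EmbryoSpec(
        tissues=(TissueSpec("sphere", Ellipsoid((0, 0, 0), (100, 100, 100)), 1.0),),
        genes=(),
        seed=42,
    )
    truth = generate_embryo(spec)
    stack, _ = slice_embryo(
        truth, thickness=10, gap=0, max_rot=0, max_trans=0, flip_prob=0, seed=1
    )
    return stack


@pytest.fixture(scope="session")
def patterned_embryo():
    """One ellipsoidal tissue (~5,000 beads) with planted uniform, focal and
    gradient genes, cut into contiguous sections without perturbation."""
    ell = Ellipsoid((0, 0, 0), (250, 150, 120))
    density = 5000 / (ell.volume / 1e3)
    genes = (
        PatternSpec(gene="uniform_g", pattern="uniform", base_mean=5.0),
        PatternSpec(gene="focal_g", pattern="focal", base_mean=20.0,
                    center=(80.0, 40.0, 0.0), sd=40.0),
        PatternSpec(gene="focal_far", pattern="focal", base_mean=20.0,
                    center=(-150.0, -60.0, 0.0), sd=35.0),
        PatternSpec(gene="grad_g", pattern="linear_gradient", base_mean=4.0,
                    axis=(1.0, 0.0, 0.0), slope=3.0 / 500.0),
        # background housekeeping genes: keep per-bead library sizes stable so
        # normalization does not alias pattern structure into other genes
        *[
            PatternSpec(gene=f"bg{i}", pattern="uniform", base_mean=8.0)
            for i in range(20)
        ],
    )
    spec = EmbryoSpec(tissues=(TissueSpec("t", ell, density),), genes=genes, seed=7)
    truth = generate_embryo(spec)
    stack, _ = slice_embryo(
        truth, thickness=10, gap=0, max_rot=0, max_trans=0, flip_prob=0, seed=3
    )
    return truth, stack
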