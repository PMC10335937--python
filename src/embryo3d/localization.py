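"""Per-gene, per-tissue 3D localization scores.

The score asks: how much more densely packed are a gene's expressing beads
inside the volume they actually occupy than they would be if spread over the
whole tissue?  With V_expr the alpha-shape volume of the expressing beads and
V_tissue the tissue's,

    score = log2[ (n_expr / V_expr) / (n_expr / V_tissue) ] = log2(V_tissue / V_expr)

A gene expressed throughout the tissue scores 0; one confined to an eighth
of the tissue volume scores 3.  Scores rank genes by spatial restriction and
are invariant to positive rescaling of the expression values (the expressing
set is unchanged).  The score definition is isolated in
:func:`localization_score` so alternatives (e.g. counts-weighted densities)
can be swapped in one place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alpha_shapes import alpha_shape_volume_3d, convex_hull_volume
from .io_model import EmbryoStack, normalize

__all__ = ["LocalizationScore", "localization_score", "rank_localized_genes"]


@dataclass
class LocalizationScore:
    gene: str
    tissue: str
    n_expressing: int
    v_expr_um3: float
    v_tissue_um3: float
    score: float | None          # None when not scoreable
    reason: str | None = None    # why the score is missing


def _alpha_volume(points: np.ndarray, alpha: float) -> float:
    v = alpha_shape_volume_3d(points, alpha)
    if v <= 0:
        v = convex_hull_volume(points)
    return v


def localization_score(
    stack: EmbryoStack,
    gene: str,
    tissue: str,
    expr_threshold: float = 0.0,
    min_expressing: int = 20,
    alpha: float = 100.0,
    target_sum: float = 1e4,
    _cache: dict | None = None,
) -> LocalizationScore:
    """Localization score of one gene within one tissue.

    The expressing set is the tissue's beads with normalized expression
    strictly above ``expr_threshold``.  ``alpha`` (µm) is the 3D alpha-shape
    scale; it should exceed the inter-slice spacing so that slabs of beads on
    neighbouring sections connect.  Fewer than ``min_expressing`` expressing
    beads, or degenerate geometry, give a missing score with a reason.
    """
    from .vish import _gene_column

    if _cache is not None and "beads" in _cache:
        beads, norm = _cache["beads"], _cache["norm"]
    else:
        beads = stack.beads_3d()
        norm = normalize(stack.counts_matrix(), target_sum=target_sum, log1p=True)
        if _cache is not None:
            _cache["beads"], _cache["norm"] = beads, norm
    col = _gene_column(stack, gene)
    in_tissue = (beads["cell_state"] == tissue).to_numpy()
    n_tissue = int(in_tissue.sum())
    if n_tissue < min_expressing:
        raise ValueError(
            f"tissue {tissue!r} has only {n_tissue} beads (< {min_expressing})"
        )
    pts = beads.loc[in_tissue, ["x", "y", "z"]].to_numpy()
    if _cache is not None and ("vt", tissue) in _cache:
        v_tissue = _cache[("vt", tissue)]
    else:
        v_tissue = _alpha_volume(pts, alpha)
        if _cache is not None:
            _cache[("vt", tissue)] = v_tissue
    expr = norm[in_tissue, col] > expr_threshold
    n_expr = int(expr.sum())
    if n_expr < min_expressing:
        return LocalizationScore(gene, tissue, n_expr, 0.0, v_tissue, None,
                                 reason=f"fewer than {min_expressing} expressing beads")
    v_expr = _alpha_volume(pts[expr], alpha)
    if v_expr <= 0:
        return LocalizationScore(gene, tissue, n_expr, 0.0, v_tissue, None,
                                 reason="degenerate expressing-set geometry")
    if v_tissue <= 0:
        return LocalizationScore(gene, tissue, n_expr, v_expr, 0.0, None,
                                 reason="degenerate tissue geometry")
    score = float(np.log2(v_tissue / v_expr))
    return LocalizationScore(gene, tissue, n_expr, v_expr, v_tissue, score)


def rank_localized_genes(
    stack: EmbryoStack,
    tissue: str,
    top_k: int = 20,
    genes: list[str] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Top-k table of genes by localization score within a tissue.

    Sorted by score descending; ties broken by n_expressing descending, then
    gene name.  Genes with missing scores are excluded; if fewer than
    ``top_k`` remain, the table is shorter (with a warning).
    """
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    gene_list = list(genes) if genes is not None else list(stack.gene_names)
    cache: dict = {}
    rows = []
    for g in gene_list:
        s = localization_score(stack, g, tissue, _cache=cache, **kwargs)
        if s.score is None:
            continue
        rows.append(
            {
                "gene": g,
                "score": s.score,
                "n_expressing": s.n_expressing,
                "v_expr_um3": s.v_expr_um3,
                "v_tissue_um3": s.v_tissue_um3,
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "score", "n_expressing",
                                        "v_expr_um3", "v_tissue_um3"])
    if len(table):
        table = table.sort_values(
            ["score", "n_expressing", "gene"], ascending=[False, False, True]
        ).reset_index(drop=True)
    if len(table) < top_k:
        warnings.warn(f"only {len(table)} scoreable genes (top_k={top_k})")
    return table.head(top_k)
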