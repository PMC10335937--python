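"""Gene-module discovery by dynamic-time-warping clustering of bin profiles.

Genes with coherent spatial patterns along an axis (e.g. the staggered Hox
domains along the neural tube) are grouped by partitional clustering of
their z-scored bin profiles under the DTW distance, with DTW barycenter
(DBA) centroids.  DTW is constrained by a Sakoe-Chiba band; the band is kept
narrow (10% of the bin count by default) so that profiles whose peaks sit in
*different* spatial domains cannot be warped onto each other — with wide
bands, neighbouring modules would collapse into one.  Clusters whose
centroids become indistinguishable (closer than twice the mean
member-to-centroid distance) are merged, so the returned module count can be
smaller than k.  Modules are ordered by the axis position of their centroid
peak, anterior to posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GeneModule", "dtw_distance", "dtw_modules", "module_expand", "zscore_profiles"]


@dataclass
class GeneModule:
    module_id: int               # 0-based, ordered by centroid peak position
    genes: list[str]
    centroid: np.ndarray         # z-scored profile over bins
    peak_bin: int


def zscore_profiles(profiles: np.ndarray) -> np.ndarray:
    """Row z-score; constant rows map to zeros."""
    profiles = np.asarray(profiles, dtype=float)
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    return np.where(sd > 0, (profiles - mu) / np.where(sd > 0, sd, 1.0), 0.0)


def _band_window(n: int, m: int, window: int):
    """Per-row column ranges of the Sakoe-Chiba band on an n x m grid."""
    lo = np.maximum(0, np.arange(n) * m // n - window)
    hi = np.minimum(m, np.arange(n) * m // n + window + 1)
    return lo, hi


def dtw_distance(a: np.ndarray, b: np.ndarray, window: int | None = None,
                 return_path: bool = False):
    """Constrained DTW distance between two 1D profiles.

    Local cost is squared difference; the returned distance is the square
    root of the accumulated cost along the optimal monotone path (symmetric
    unit steps).  ``window`` is the Sakoe-Chiba half-width in bins (None for
    unconstrained).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if window is None:
        window = max(n, m)
    window = max(window, abs(n - m))
    INF = np.inf
    acc = np.full((n + 1, m + 1), INF)
    acc[0, 0] = 0.0
    lo, hi = _band_window(n, m, window)
    for i in range(1, n + 1):
        for j in range(lo[i - 1] + 1, hi[i - 1] + 1):
            cost = (a[i - 1] - b[j - 1]) ** 2
            acc[i, j] = cost + min(acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1])
    dist = float(np.sqrt(acc[n, m]))
    if not return_path:
        return dist
    # backtrack
    path = []
    i, j = n, m
    while i > 0 or j > 0:
        path.append((i - 1, j - 1))
        steps = []
        if i > 0 and j > 0:
            steps.append((acc[i - 1, j - 1], i - 1, j - 1))
        if i > 0:
            steps.append((acc[i - 1, j], i - 1, j))
        if j > 0:
            steps.append((acc[i, j - 1], i, j - 1))
        _, i, j = min(steps)
    path.reverse()
    return dist, path[1:] if path and path[0] == (-1, -1) else path


def _dba_centroid(profiles: np.ndarray, init: np.ndarray, window: int,
                  n_iter: int = 5) -> np.ndarray:
    """DTW barycenter averaging: align members to the centroid and average."""
    centroid = init.copy()
    m = len(centroid)
    for _ in range(n_iter):
        sums = np.zeros(m)
        counts = np.zeros(m)
        for prof in profiles:
            _, path = dtw_distance(centroid, prof, window=window, return_path=True)
            for ci, pj in path:
                if ci >= 0 and pj >= 0:
                    sums[ci] += prof[pj]
                    counts[ci] += 1
        new = np.where(counts > 0, sums / np.maximum(counts, 1), centroid)
        if np.allclose(new, centroid, atol=1e-10):
            break
        centroid = new
    return centroid


def dtw_modules(
    profiles: np.ndarray,
    gene_names: list[str] | None = None,
    k: int = 8,
    window_frac: float = 0.1,
    seed: int = 0,
    max_iter: int = 30,
) -> list[GeneModule]:
    """Partition gene bin-profiles into spatial modules by DTW k-means.

    Profiles are z-scored per gene.  Centroids are initialized k-means++
    style (seeded), updated by DBA; clusters whose centroid peaks fall
    within the warping window of each other (the same spatial domain, split
    by noise) are merged and empty clusters dropped, so the number of
    returned modules is at most k.  Deterministic for a fixed seed.
    """
    profiles = np.asarray(profiles, dtype=float)
    n_genes, n_bins = profiles.shape
    if k > n_genes:
        raise ValueError(f"k={k} exceeds the number of genes ({n_genes})")
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(n_genes)]
    z = zscore_profiles(profiles)
    window = max(1, int(round(window_frac * n_bins)))
    rng = np.random.default_rng(seed)

    # pairwise distances once; genes are few compared to beads
    dmat = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            dmat[i, j] = dmat[j, i] = dtw_distance(z[i], z[j], window=window)

    # k-means++ seeding on the precomputed distances
    centers = [int(rng.integers(n_genes))]
    for _ in range(1, k):
        d2 = dmat[:, centers].min(axis=1) ** 2
        total = d2.sum()
        if total <= 0:
            remaining = [i for i in range(n_genes) if i not in centers]
            if not remaining:
                break
            centers.append(int(remaining[0]))
            continue
        centers.append(int(rng.choice(n_genes, p=d2 / total)))
    centroids = z[centers].copy()

    assign = np.full(n_genes, -1)
    for _ in range(max_iter):
        dists = np.array(
            [[dtw_distance(c, z[g], window=window) for c in centroids]
             for g in range(n_genes)]
        )
        new_assign = dists.argmin(axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        centroids = np.array(
            [
                _dba_centroid(z[assign == c], centroids[c], window)
                if np.any(assign == c) else centroids[c]
                for c in range(len(centroids))
            ]
        )

    # drop empties, then merge clusters describing the same spatial domain:
    # centroids whose peaks fall within the warping window are mutually
    # alignable, i.e. they are one module split by noise
    def _members(c):
        return np.flatnonzero(assign == c)

    live = [c for c in range(len(centroids)) if len(_members(c))]
    merged = True
    while merged and len(live) > 1:
        merged = False
        for a in range(len(live)):
            for b in range(a + 1, len(live)):
                ca, cb = live[a], live[b]
                peak_a = int(np.argmax(centroids[ca]))
                peak_b = int(np.argmax(centroids[cb]))
                if abs(peak_a - peak_b) <= window:
                    assign[assign == cb] = ca
                    centroids[ca] = _dba_centroid(z[_members(ca)], centroids[ca], window)
                    live.pop(b)
                    merged = True
                    break
            if merged:
                break

    modules = []
    for c in live:
        idx = _members(c)
        centroid = centroids[c]
        modules.append((int(np.argmax(centroid)), idx, centroid))
    modules.sort(key=lambda t: t[0])
    return [
        GeneModule(
            module_id=i,
            genes=[gene_names[g] for g in idx],
            centroid=centroid,
            peak_bin=peak,
        )
        for i, (peak, idx, centroid) in enumerate(modules)
    ]


def module_expand(
    modules: list[GeneModule],
    counts,
    coordinate: np.ndarray,
    gene_names: list[str],
    fdr_max: float = 0.01,
    lfc_min: float = 0.05,
) -> dict[int, list[str]]:
    """Assign additional genes to modules by centroid-covariate trend tests.

    Each gene not already in a module is tested (NB quasi-likelihood trend
    test) with each module's centroid profile — evaluated at the gene's bead
    coordinates — as the covariate; the gene joins the best-FDR module if it
    passes the selection rule there.  Returns {module_id: added genes}.
    """
    import scipy.sparse as sp

    from .axes import bin_coordinate
    from .trend import spatial_trend_test

    counts = counts.tocsc() if sp.issparse(counts) else np.asarray(counts)
    member = {g for m in modules for g in m.genes}
    unassigned = [i for i, g in enumerate(gene_names) if g not in member]
    if not unassigned:
        return {m.module_id: [] for m in modules}
    n_bins = len(modules[0].centroid)
    bins = bin_coordinate(coordinate, n_bins)
    lib = np.asarray(counts.sum(axis=1)).ravel()
    sub = counts[:, unassigned]
    sub = sub.toarray() if sp.issparse(sub) else sub

    results = {}
    for m in modules:
        covar = m.centroid[bins]
        res = spatial_trend_test(
            sub,
            covar,
            gene_names=[gene_names[i] for i in unassigned],
            fdr_max=fdr_max,
            lfc_min=lfc_min,
            library_size=lib,
        )
        results[m.module_id] = res.table.set_index("gene")

    added: dict[int, list[str]] = {m.module_id: [] for m in modules}
    for gi in unassigned:
        gname = gene_names[gi]
        best_id, best_fdr = None, np.inf
        for m in modules:
            row = results[m.module_id].loc[gname]
            if bool(row["selected"]) and row["logfc"] > 0 and row["fdr"] < best_fdr:
                best_id, best_fdr = m.module_id, row["fdr"]
        if best_id is not None:
            added[best_id].append(gname)
    return added
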