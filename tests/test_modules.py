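import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from embryo3d.modules import dtw_distance, dtw_modules, module_expand, zscore_profiles


def bump(n_bins, center, width=1.5, amp=10.0):
    x = np.arange(n_bins)
    return amp * np.exp(-((x - center) ** 2) / (2 * width**2))


def staggered_module_profiles(seed=0, n_modules=6, genes_per_module=5, n_bins=25,
                              noise=0.5):
    """Noisy bin profiles for staggered bump modules (Hox-like)."""
    rng = np.random.default_rng(seed)
    centers = (np.arange(n_modules) + 0.5) / n_modules * n_bins
    profiles, labels, names = [], [], []
    for m, c in enumerate(centers):
        for g in range(genes_per_module):
            profiles.append(bump(n_bins, c) + rng.normal(0, noise, n_bins))
            labels.append(m)
            names.append(f"m{m}g{g}")
    return np.array(profiles), np.array(labels), names


# ---------------------------------------------------------------------------
# the DTW distance itself


def test_self_distance_zero_and_symmetry():
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=(2, 25))
    assert dtw_distance(a, a, window=3) == 0.0
    assert dtw_distance(a, b, window=3) == pytest.approx(dtw_distance(b, a, window=3))


def test_dtw_absorbs_shifts_within_window_only():
    a = bump(25, 10)
    shifted_near = bump(25, 12)
    shifted_far = bump(25, 18)
    d_near = dtw_distance(a, shifted_near, window=2)
    d_far = dtw_distance(a, shifted_far, window=2)
    assert d_near < d_far
    # a wider band absorbs more of the far shift
    assert dtw_distance(a, shifted_far, window=8) < d_far


def test_unconstrained_dtw_not_larger_than_euclidean():
    rng = np.random.default_rng(1)
    a, b = rng.normal(size=(2, 20))
    assert dtw_distance(a, b) <= np.linalg.norm(a - b) + 1e-12


# ---------------------------------------------------------------------------
# clustering


def test_two_shifted_groups_recovered_exactly():
    rng = np.random.default_rng(2)
    profiles = np.array(
        [bump(20, 5) + rng.normal(0, 0.3, 20) for _ in range(6)]
        + [bump(20, 15) + rng.normal(0, 0.3, 20) for _ in range(6)]
    )
    mods = dtw_modules(profiles, k=2, seed=0)
    assert len(mods) == 2
    pred = {g: m.module_id for m in mods for g in m.genes}
    labels = [0] * 6 + [1] * 6
    assert adjusted_rand_score(labels, [pred[f"g{i}"] for i in range(12)]) == 1.0


def test_six_planted_modules_recovered_with_k8():
    profiles, labels, names = staggered_module_profiles(seed=3)
    mods = dtw_modules(profiles, names, k=8, seed=0)
    assert len(mods) == 6
    pred = {g: m.module_id for m in mods for g in m.genes}
    ari = adjusted_rand_score(labels, [pred[n] for n in names])
    assert ari >= 0.8
    # modules come out ordered anterior to posterior
    peaks = [m.peak_bin for m in mods]
    assert peaks == sorted(peaks)


def test_identical_profiles_collapse_to_one_module():
    profiles = np.tile(bump(25, 12), (10, 1))
    mods = dtw_modules(profiles, k=4, seed=0)
    assert len(mods) == 1
    assert len(mods[0].genes) == 10


def test_k_larger_than_gene_count_rejected():
    with pytest.raises(ValueError):
        dtw_modules(np.zeros((3, 10)), k=5)


def test_clustering_deterministic_under_fixed_seed():
    profiles, _, names = staggered_module_profiles(seed=4)
    a = dtw_modules(profiles, names, k=8, seed=7)
    b = dtw_modules(profiles, names, k=8, seed=7)
    assert [m.genes for m in a] == [m.genes for m in b]


def test_zscore_handles_constant_rows():
    z = zscore_profiles(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))
    assert np.allclose(z[0], 0.0)
    assert z[1].mean() == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# module expansion


@pytest.fixture(scope="module")
def expansion_setup():
    """Bead-level counts for module genes plus held-out and flat genes."""
    rng = np.random.default_rng(5)
    n_beads, n_bins = 3000, 25
    coord = rng.uniform(0, 1, n_beads)
    bins = np.minimum((coord * n_bins).astype(int), n_bins - 1)
    centers = (np.arange(6) + 0.5) / 6
    names, cols = [], []
    for m, c in enumerate(centers):
        for g in range(5):
            mean = 20 * np.exp(-((coord - c) ** 2) / (2 * 0.06**2))
            cols.append(rng.poisson(rng.gamma(10, np.clip(mean, 1e-9, None) / 10)))
            names.append(f"m{m}g{g}")
    # held-out gene from module 3's bump, plus a flat gene
    mean3 = 20 * np.exp(-((coord - centers[3]) ** 2) / (2 * 0.06**2))
    cols.append(rng.poisson(rng.gamma(10, np.clip(mean3, 1e-9, None) / 10)))
    names.append("heldout3")
    cols.append(rng.poisson(np.full(n_beads, 5.0)))
    names.append("flat")
    # background genes keep library sizes stable, as in a transcriptome-wide
    # panel where any one gene is a negligible library fraction
    for i in range(60):
        cols.append(rng.poisson(np.full(n_beads, 10.0)))
        names.append(f"bg{i}")
    counts = np.column_stack(cols)
    profiles = np.array(
        [
            [counts[bins == b, j].mean() for b in range(n_bins)]
            for j in range(30)
        ]
    )
    mods = dtw_modules(profiles, names[:30], k=8, seed=0)
    return mods, counts, coord, names


def test_held_out_gene_joins_its_module(expansion_setup):
    mods, counts, coord, names = expansion_setup
    added = module_expand(mods, counts, coord, names)
    home = [m for m in mods if "m3g0" in m.genes][0]
    assert "heldout3" in added[home.module_id]


def test_flat_gene_stays_unassigned(expansion_setup):
    mods, counts, coord, names = expansion_setup
    added = module_expand(mods, counts, coord, names)
    assert all("flat" not in genes for genes in added.values())
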