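import numpy as np
import pytest
from scipy.stats import spearmanr

from embryo3d.axes import (
    bin_coordinate,
    boundary_select,
    dv_coordinate,
    principal_curve_coordinate,
    pseudotime_space_pairs,
)


# ---------------------------------------------------------------------------
# principal curve


def test_straight_segment_reduces_to_euclidean_projection():
    rng = np.random.default_rng(0)
    t = np.sort(rng.uniform(0, 100, 200))
    pts = np.column_stack([t, 0.5 * t])  # a straight line in 2D
    coord = principal_curve_coordinate(pts, anterior_landmark=pts[0])
    true = np.linalg.norm(pts - pts[np.argmin(t)], axis=1)
    r = np.corrcoef(coord, true)[0, 1]
    assert r == pytest.approx(1.0, abs=1e-6)


def test_parabolic_arc_orders_beads_by_arc_parameter():
    rng = np.random.default_rng(1)
    t = np.sort(rng.uniform(-1, 1, 400))
    pts = np.column_stack([100 * t, 60 * t**2])
    coord = principal_curve_coordinate(pts, anterior_landmark=pts[0])
    rho = spearmanr(coord, t).statistic
    assert abs(rho) >= 0.99


def test_too_few_or_degenerate_beads_rejected():
    with pytest.raises(ValueError):
        principal_curve_coordinate(np.zeros((5, 2)))
    with pytest.raises(ValueError):
        principal_curve_coordinate(np.tile([1.0, 2.0], (20, 1)))


def test_rigid_motion_preserves_arclength_coordinates():
    rng = np.random.default_rng(2)
    t = np.sort(rng.uniform(0, 1, 300))
    pts = np.column_stack([200 * t, 50 * np.sin(3 * t)])
    coord0 = principal_curve_coordinate(pts, anterior_landmark=pts[0])
    ang = np.deg2rad(73.0)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    moved = pts @ rot.T + [111.0, -222.0]
    coord1 = principal_curve_coordinate(moved, anterior_landmark=moved[0])
    assert np.corrcoef(coord0, coord1)[0, 1] > 0.999


# ---------------------------------------------------------------------------
# DV coordinate


def test_hull_boundary_bead_gets_zero_distance_and_bin_zero():
    pts = np.array([[0, 0], [100, 0], [100, 100], [0, 100], [50, 50], [0, 50]])
    dist, bins = dv_coordinate(pts)
    assert dist[0] == 0.0 and bins[0] == 0
    assert dist[5] == 0.0  # on the hull edge


def test_polygon_center_lands_in_last_bin():
    theta = np.linspace(0, 2 * np.pi, 60, endpoint=False)
    ring = np.column_stack([100 * np.cos(theta), 100 * np.sin(theta)])
    pts = np.vstack([ring, [[0.0, 0.0]]])
    dist, bins = dv_coordinate(pts, n_bins=8)
    # center of a many-sided regular polygon: distance ~ apothem ~ R
    assert dist[-1] == pytest.approx(100 * np.cos(np.pi / 60), rel=1e-3)
    assert bins[-1] == 7


def test_all_beads_on_hull_collapse_to_bin_zero():
    theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    ring = np.column_stack([50 * np.cos(theta), 50 * np.sin(theta)])
    dist, bins = dv_coordinate(ring)
    assert np.allclose(dist, 0.0, atol=1e-9)
    assert (bins == 0).all()


def test_degenerate_hull_errors():
    with pytest.raises(ValueError):
        dv_coordinate(np.column_stack([np.arange(6), np.zeros(6)]))


# ---------------------------------------------------------------------------
# binning


def test_bin_edge_conventions():
    assert bin_coordinate(np.array([0.0, 0.5, 1.0]), 2).tolist() == [0, 1, 1]


def test_25_bins_over_neural_tube_axis_have_184um_width():
    coords = np.array([0.0, 4600.0])
    bins = bin_coordinate(coords, 25)
    assert bins.tolist() == [0, 24]
    assert 4600 / 25 == pytest.approx(184.0)


def test_single_bin_rejected_and_zero_range_warns():
    with pytest.raises(ValueError):
        bin_coordinate(np.array([1.0, 2.0]), 1)
    with pytest.warns(UserWarning):
        bins = bin_coordinate(np.full(5, 3.0), 4)
    assert (bins == 0).all()


def test_bins_partition_and_are_balanced_for_uniform_coords():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 1, 10_000)
    bins = bin_coordinate(coords, 25)
    counts = np.bincount(bins, minlength=25)
    assert counts.sum() == 10_000
    assert counts.min() > 300


# ---------------------------------------------------------------------------
# boundary selection


def test_bead_on_polyline_included_at_distance_zero():
    line = np.array([[0.0, 0.0], [100.0, 0.0]])
    idx, dist = boundary_select(np.array([[50.0, 0.0]]), line)
    assert idx.tolist() == [0]
    assert dist[0] == 0.0


def test_bead_beyond_max_distance_excluded():
    line = np.array([[0.0, 0.0], [100.0, 0.0]])
    idx, _ = boundary_select(np.array([[50.0, 400.0]]), line, max_dist=300.0)
    assert idx.size == 0


def test_distance_uses_segment_not_infinite_line():
    line = np.array([[0.0, 0.0], [100.0, 0.0]])
    idx, dist = boundary_select(np.array([[200.0, 0.0]]), line)
    assert dist[0] == pytest.approx(100.0)  # to the endpoint, not 0


def test_short_polyline_rejected():
    with pytest.raises(ValueError):
        boundary_select(np.zeros((3, 2)), np.array([[0.0, 0.0]]))


# ---------------------------------------------------------------------------
# pseudotime vs space


def test_single_pair_distances():
    pts = np.array([[0.0, 0.0], [10.0, 0.0]])
    out = pseudotime_space_pairs(pts, np.array([0.2, 0.7]))
    assert out.shape == (1, 2)
    assert out[0, 0] == pytest.approx(10.0)
    assert out[0, 1] == pytest.approx(0.5)


def test_pair_count_is_n_choose_2():
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 100, (37, 3))
    out = pseudotime_space_pairs(pts, rng.uniform(0, 1, 37))
    assert len(out) == 37 * 36 // 2
    assert (out >= 0).all()


def test_progenitors_show_smaller_spatial_distances_than_differentiated():
    rng = np.random.default_rng(5)
    # compact progenitor field vs dispersed differentiated cells, same
    # pseudotime spread
    prog = rng.normal(0, 30, (150, 2))
    diff = rng.normal(0, 300, (150, 2))
    pts = np.vstack([prog, diff])
    ptime = rng.uniform(0, 1, 300)
    states = np.array(["prog"] * 150 + ["diff"] * 150)
    p_pairs = pseudotime_space_pairs(pts, ptime, states, "prog")
    d_pairs = pseudotime_space_pairs(pts, ptime, states, "diff")
    assert np.median(p_pairs[:, 0]) < np.median(d_pairs[:, 0])


def test_nonfinite_pseudotime_rejected():
    with pytest.raises(ValueError):
        pseudotime_space_pairs(np.zeros((3, 2)), np.array([0.0, np.nan, 1.0]))
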