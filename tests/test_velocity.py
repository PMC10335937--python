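import numpy as np
import pytest

from embryo3d.synthetic import (
    Ellipsoid,
    EmbryoSpec,
    TissueSpec,
    generate_embryo,
    plant_velocity,
)
from embryo3d.velocity import (
    VelocityField,
    grid_velocity,
    low_velocity_regions,
    velocity_confidence,
    velocity_length,
)


def brute_knn(targets, beads, k, exclude=None):
    """Naive kNN oracle with the (distance, index) tie rule."""
    out = []
    for i, t in enumerate(np.atleast_2d(targets)):
        d = np.sqrt(((beads - t) ** 2).sum(axis=1))
        idx = sorted(range(len(beads)), key=lambda j: (d[j], j))
        if exclude is not None:
            idx = [j for j in idx if j != exclude[i]]
        out.append(idx[:k])
    return np.array(out)


@pytest.fixture(scope="module")
def random_field():
    rng = np.random.default_rng(17)
    coords = rng.uniform(0, 1000, (500, 2))
    vectors = rng.normal(size=(500, 2))
    return VelocityField(coords, vectors, k=20, pitch=50)


def test_grid_velocity_matches_brute_force(random_field):
    f = random_field
    grid = grid_velocity(f)
    centers = grid[["x", "y"]].to_numpy()
    nbrs = brute_knn(centers, f.coords, f.k)
    oracle = f.vectors[nbrs].mean(axis=1)
    assert np.allclose(grid[["vx", "vy"]].to_numpy(), oracle, atol=0, rtol=0)


def test_velocity_length_matches_brute_force(random_field):
    f = random_field
    lengths = velocity_length(f)
    nbrs = brute_knn(f.coords, f.coords, f.k, exclude=np.arange(f.n_beads))
    oracle = np.linalg.norm(f.vectors[nbrs], axis=2).mean(axis=1)
    assert np.allclose(lengths, oracle, atol=0, rtol=0)


def test_velocity_confidence_matches_brute_force(random_field):
    f = random_field
    conf = velocity_confidence(f)
    nbrs = brute_knn(f.coords, f.coords, f.k, exclude=np.arange(f.n_beads))
    norms = np.linalg.norm(f.vectors, axis=1)
    oracle = np.array(
        [
            np.mean(
                f.vectors[nbrs[i]] @ f.vectors[i] / (norms[nbrs[i]] * norms[i])
            )
            for i in range(f.n_beads)
        ]
    )
    assert np.allclose(conf, oracle, atol=1e-12)


def test_constant_field_summaries():
    rng = np.random.default_rng(1)
    coords = rng.uniform(0, 500, (200, 2))
    f = VelocityField(coords, np.tile([3.0, 4.0], (200, 1)), k=10, pitch=50)
    assert np.allclose(grid_velocity(f)[["vx", "vy"]], [3.0, 4.0])
    assert np.allclose(velocity_length(f), 5.0)
    assert np.allclose(velocity_confidence(f), 1.0)
    assert np.allclose(velocity_confidence(f, normalized=False), 10.0)


def test_zero_vector_bead_excluded_from_neighbour_lengths():
    # 12 beads on a ring with speed 2, plus a zero-vector bead at the center
    theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    coords = np.vstack([np.column_stack([np.cos(theta), np.sin(theta)]) * 50,
                        [[0.0, 0.0]]])
    vectors = np.vstack([np.column_stack([-np.sin(theta), np.cos(theta)]) * 2,
                         [[0.0, 0.0]]])
    f = VelocityField(coords, vectors, k=5, pitch=50)
    lengths = velocity_length(f)
    assert lengths[-1] == pytest.approx(2.0)  # self (zero) excluded
    conf = velocity_confidence(f)
    assert np.isnan(conf[-1])  # undefined for a zero vector


def test_antiparallel_bead_has_confidence_minus_one():
    rng = np.random.default_rng(2)
    coords = rng.uniform(0, 100, (30, 2))
    vectors = np.tile([1.0, 0.0], (30, 1))
    vectors[0] = [-1.0, 0.0]
    f = VelocityField(coords, vectors, k=10, pitch=50)
    assert velocity_confidence(f)[0] == pytest.approx(-1.0)


def test_isotropic_vectors_have_near_zero_mean_confidence():
    rng = np.random.default_rng(3)
    coords = rng.uniform(0, 2000, (2000, 2))
    angles = rng.uniform(0, 2 * np.pi, 2000)
    vectors = np.column_stack([np.cos(angles), np.sin(angles)])
    f = VelocityField(coords, vectors, k=50, pitch=50)
    assert abs(np.nanmean(velocity_confidence(f))) < 0.05


def test_uniform_fast_field_has_no_low_velocity_regions():
    rng = np.random.default_rng(4)
    coords = rng.uniform(0, 500, (300, 2))
    f = VelocityField(coords, np.tile([2.0, 0.0], (300, 1)), k=20, pitch=50)
    labels = low_velocity_regions(coords, velocity_length(f))
    assert set(labels) == {""}


@pytest.fixture(scope="module")
def sink_embryo():
    spec = EmbryoSpec(
        tissues=(TissueSpec("t", Ellipsoid((0, 0, 0), (400, 400, 50)), 0.3),),
        genes=(),
        seed=6,
    )
    return generate_embryo(spec)


def test_planted_sink_recovered_as_single_region(sink_embryo):
    v = plant_velocity(sink_embryo, "convergent", center=(120.0, 60.0),
                       magnitude=2.0, noise_sd=0.05, seed=1)
    coords = sink_embryo.positions[:, :2]
    f = VelocityField(coords, v, k=50, pitch=50)
    labels = low_velocity_regions(coords, velocity_length(f), velocity_confidence(f))
    regions = sorted(set(labels) - {""})
    assert regions == ["R1"]
    centroid = coords[labels == "R1"].mean(axis=0)
    assert np.hypot(centroid[0] - 120, centroid[1] - 60) < 100


def test_two_distant_sinks_give_two_regions(sink_embryo):
    coords = sink_embryo.positions[:, :2]
    # two synthetic speed wells far apart relative to the linking radius
    d1 = np.linalg.norm(coords - [-250, -250], axis=1)
    d2 = np.linalg.norm(coords - [250, 250], axis=1)
    speed = np.minimum(d1, d2) / 400
    rng = np.random.default_rng(7)
    angles = rng.uniform(0, 2 * np.pi, len(coords))
    labels = low_velocity_regions(coords, speed)
    regions = sorted(set(labels) - {""})
    assert len(regions) == 2


def test_field_validation():
    with pytest.raises(ValueError):
        VelocityField(np.zeros((3, 2)), np.zeros((4, 2)))
    with pytest.raises(ValueError):
        VelocityField(np.zeros((3, 2)), np.full((3, 2), np.nan))
    with pytest.raises(ValueError):
        VelocityField(np.zeros((3, 2)), np.zeros((3, 2)), k=0)
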