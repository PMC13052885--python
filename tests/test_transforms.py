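"""Stimulus-transform contracts: normalization, density subsets, the
inversion isometry, voxel-surface resampling against a brute-force grid
oracle, part subdivision/scrambling geometry, and augmentation."""

import numpy as np
import pytest

from cloudshape.core import PointCloud
from cloudshape import transforms as tf


def make_cloud(rng, n=50, labels=None):
    return PointCloud(rng.standard_normal((n, 3)), labels)


# -- unit-sphere normalization ------------------------------------------------


def test_normalize_two_point_analytic_case():
    pc = PointCloud([[0.0, 0, 0], [2, 0, 0]])
    out = tf.normalize_unit_sphere(pc)
    np.testing.assert_allclose(out.coords, [[-1, 0, 0], [1, 0, 0]])


def test_normalize_contract_and_idempotence(rng):
    out = tf.normalize_unit_sphere(make_cloud(rng))
    norms = np.linalg.norm(out.coords, axis=1)
    assert abs(norms.max() - 1.0) < 1e-9
    assert np.abs(out.coords.mean(axis=0)).max() < 1e-9
    again = tf.normalize_unit_sphere(out)
    assert np.abs(again.coords - out.coords).max() < 1e-9


def test_normalize_degenerate_and_empty():
    single = tf.normalize_unit_sphere(PointCloud([[3.0, 1, 2]]))
    np.testing.assert_allclose(single.coords, [[0, 0, 0]])
    with pytest.raises(ValueError):
        tf.normalize_unit_sphere(PointCloud(np.empty((0, 3))))


# -- density downsampling -----------------------------------------------------


def test_downsample_is_a_subset_with_floor_sizing(rng):
    pc = make_cloud(rng, 1024, labels=rng.integers(0, 4, 1024))
    out = tf.downsample_density(pc, 0.2, seed=1)
    assert len(out) == 204                     # floor(0.2 * 1024)
    rows = {tuple(r) for r in pc.coords}
    assert all(tuple(r) in rows for r in out.coords)
    # labels follow their points
    lookup = {tuple(r): l for r, l in zip(pc.coords, pc.part_labels)}
    assert all(lookup[tuple(r)] == l for r, l in zip(out.coords, out.part_labels))


def test_downsample_identity_minimum_and_errors(rng):
    pc = make_cloud(rng, 100)
    np.testing.assert_array_equal(tf.downsample_density(pc, 1.0, 0).coords, pc.coords)
    assert len(tf.downsample_density(pc, 0.001, 0)) == 1
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            tf.downsample_density(pc, bad, 0)


def test_downsample_deterministic(rng):
    pc = make_cloud(rng, 100)
    a = tf.downsample_density(pc, 0.3, seed=9)
    b = tf.downsample_density(pc, 0.3, seed=9)
    np.testing.assert_array_equal(a.coords, b.coords)


# -- inversion ----------------------------------------------------------------


def test_invert_analytic_involution_isometry(rng):
    np.testing.assert_allclose(tf.invert(PointCloud([[0.0, 1, 0]])).coords,
                               [[0, -1, 0]])
    pc = make_cloud(rng, 30)
    np.testing.assert_allclose(tf.invert(tf.invert(pc)).coords, pc.coords)
    from scipy.spatial.distance import pdist
    np.testing.assert_allclose(pdist(tf.invert(pc).coords), pdist(pc.coords),
                               rtol=1e-12)


# -- Lego voxelization --------------------------------------------------------


def brute_occupancy(coords, v):
    origin = coords.min(axis=0)
    return {tuple(int(np.floor((p[a] - origin[a]) / v)) for a in range(3))
            for p in coords}


def brute_exposed_faces(cells):
    faces = set()
    for c in cells:
        for axis in range(3):
            for d in (-1, 1):
                nbr = list(c)
                nbr[axis] += d
                if tuple(nbr) not in cells:
                    faces.add((c, axis, d))
    return faces


def test_voxel_occupancy_matches_bruteforce_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(2, 200))
        coords = rng.standard_normal((n, 3))
        v = float(rng.uniform(0.05, 1.0))
        grid = tf.VoxelGrid.from_cloud(PointCloud(coords), v)
        assert grid.occupied == brute_occupancy(coords, v)
        assert set(grid.exposed_faces()) == brute_exposed_faces(grid.occupied)


def test_single_point_yields_one_cube(rng):
    out = tf.voxelize_lego(PointCloud([[0.2, 0.1, -0.3]]), 0.5, n_out=64, seed=0)
    assert len(out) == 64                      # all on one cube's surface


def test_two_adjacent_voxels_have_ten_exposed_faces():
    pc = PointCloud([[0.1, 0.1, 0.1], [0.6, 0.1, 0.1]])
    grid = tf.VoxelGrid.from_cloud(pc, 0.5)
    assert len(grid.occupied) == 2
    assert len(grid.exposed_faces()) == 10     # 12 faces minus the 2 shared


def test_tiny_voxels_isolate_every_point(rng):
    coords = rng.standard_normal((60, 3))
    from scipy.spatial.distance import pdist
    v = pdist(coords, metric="chebyshev").min() / 2
    grid = tf.VoxelGrid.from_cloud(PointCloud(coords), v)
    assert len(grid.occupied) == 60


def test_lego_outputs_lie_on_exposed_face_planes(rng):
    # replay the transform's sampling stream to recover the pre-normalization
    # points, check each sits exactly on a grid plane, and confirm the
    # shipped output is exactly their unit-sphere normalization
    pc = PointCloud(rng.standard_normal((80, 3)))
    v = 0.4
    grid = tf.VoxelGrid.from_cloud(pc, v)
    out = tf.voxelize_lego(pc, v, n_out=256, seed=3)
    assert len(out) == 256
    rng2 = np.random.default_rng(3)
    faces = grid.exposed_faces()
    which = rng2.integers(0, len(faces), size=256)
    u = rng2.random((256, 2))
    raw_pts = np.empty((256, 3))
    for row, fi in enumerate(which):
        cell, axis, direction = faces[fi]
        lo = grid.origin + np.asarray(cell, float) * v
        p = np.empty(3)
        p[axis] = lo[axis] + (v if direction > 0 else 0.0)
        other = [a for a in range(3) if a != axis]
        p[other[0]] = lo[other[0]] + u[row, 0] * v
        p[other[1]] = lo[other[1]] + u[row, 1] * v
        raw_pts[row] = p
    rel = (raw_pts - grid.origin) / v
    on_plane = np.isclose(rel, np.round(rel), atol=1e-9).any(axis=1)
    assert on_plane.all()
    expected = raw_pts - raw_pts.mean(axis=0)
    expected /= np.linalg.norm(expected, axis=1).max()
    np.testing.assert_allclose(out.coords, expected, atol=1e-12)


def test_lego_rejects_bad_voxel_size(rng):
    with pytest.raises(ValueError):
        tf.voxelize_lego(make_cloud(rng, 5), 0.0)


# -- part subdivision and scrambling ------------------------------------------


def test_subdivision_leaves_small_parts_alone(rng):
    labels = np.repeat(np.arange(4), 25)       # 4 parts x 25% each
    pc = PointCloud(rng.standard_normal((100, 3)), labels)
    out = tf.subdivide_large_parts(pc, tf.ScrambleConfig(seed=0))
    # shares all <= 30%: same partition up to re-indexing
    for part in range(4):
        mask = labels == part
        assert len(np.unique(out.part_labels[mask])) == 1
    assert len(np.unique(out.part_labels)) == 4


def test_subdivision_recovers_separated_blobs(rng):
    blobs = [rng.standard_normal((30, 3)) * 0.05 + center
             for center in ([0, 0, 0], [10, 0, 0], [0, 10, 0])]
    pc = PointCloud(np.concatenate(blobs), np.zeros(90, dtype=int))
    out = tf.subdivide_large_parts(pc, tf.ScrambleConfig(seed=1))
    assert len(np.unique(out.part_labels)) == 3
    for i in range(3):
        segment = out.part_labels[i * 30:(i + 1) * 30]
        assert len(np.unique(segment)) == 1    # blob = cluster, exactly


def test_subdivision_part_count_arithmetic(rng):
    # one over-threshold part among three -> 3 - 1 + 3 = 5 parts
    labels = np.array([0] * 60 + [1] * 20 + [2] * 20)
    pc = PointCloud(rng.standard_normal((100, 3)), labels)
    out = tf.subdivide_large_parts(pc, tf.ScrambleConfig(seed=2))
    assert len(np.unique(out.part_labels)) == 5
    ids = np.unique(out.part_labels)
    np.testing.assert_array_equal(ids, np.arange(len(ids)))   # contiguous


def test_subdivision_errors(rng):
    with pytest.raises(ValueError, match="part labels"):
        tf.subdivide_large_parts(make_cloud(rng, 10), tf.ScrambleConfig())
    tiny = PointCloud(rng.standard_normal((3, 3)), np.array([0, 0, 1]))
    with pytest.raises(ValueError, match="only 2 points"):
        tf.subdivide_large_parts(tiny, tf.ScrambleConfig())
    # a part with exactly n_subclusters points splits trivially
    exact = PointCloud(rng.standard_normal((4, 3)), np.array([0, 0, 0, 1]))
    out = tf.subdivide_large_parts(exact, tf.ScrambleConfig())
    assert len(np.unique(out.part_labels)) == 4


def test_scramble_zero_offsets_overlap_parts(rng):
    labels = np.array([0] * 10 + [1] * 10)
    pc = PointCloud(rng.standard_normal((20, 3)) + [5.0, 0, 0], labels)
    rec = tf.scramble_parts(pc, tf.ScrambleConfig(seed=4),
                            _forced_offsets=np.zeros((2, 3)))
    cloud = rec.cloud
    c0 = cloud.coords[cloud.part_labels == 0].mean(axis=0)
    c1 = cloud.coords[cloud.part_labels == 1].mean(axis=0)
    np.testing.assert_allclose(c0, c1, atol=1e-9)


def test_scramble_preserves_part_geometry_up_to_global_scale(chair_cloud):
    from scipy.spatial.distance import pdist
    cfg = tf.ScrambleConfig(seed=8)
    refined = tf.subdivide_large_parts(chair_cloud, cfg)
    rec = tf.scramble_parts(refined, cfg)
    scales = []
    for part in np.unique(refined.part_labels):
        mask = refined.part_labels == part
        before = pdist(refined.coords[mask])
        after = pdist(rec.cloud.coords[mask])
        ratio = after[before > 0] / before[before > 0]
        scales.append(ratio)
        assert np.ptp(ratio) / ratio.mean() < 1e-6   # rigid within the part
    all_ratios = np.concatenate(scales)
    assert np.ptp(all_ratios) / all_ratios.mean() < 1e-6   # one shared scale


def test_scramble_anchor_centered_before_normalization(chair_cloud):
    cfg = tf.ScrambleConfig(seed=3)
    refined = tf.subdivide_large_parts(chair_cloud, cfg)
    rec = tf.scramble_parts(refined, cfg, )
    anchor = rec.params["anchor_part"]
    np.testing.assert_allclose(rec.params["offsets"][anchor], np.zeros(3))


def test_scramble_requires_two_parts(rng):
    pc = PointCloud(rng.standard_normal((10, 3)), np.zeros(10, dtype=int))
    with pytest.raises(ValueError, match="two parts"):
        tf.scramble_parts(pc, tf.ScrambleConfig())


def test_scramble_deterministic(chair_cloud):
    cfg = tf.ScrambleConfig(seed=11)
    refined = tf.subdivide_large_parts(chair_cloud, cfg)
    a = tf.scramble_parts(refined, cfg)
    b = tf.scramble_parts(refined, cfg)
    np.testing.assert_array_equal(a.cloud.coords, b.cloud.coords)


# -- training augmentation ----------------------------------------------------


def test_augment_no_dropout_is_pure_affine(rng):
    pc = make_cloud(rng, 64)
    cfg = tf.AugmentConfig(dropout_range=(0.0, 0.0), seed=5)
    out = tf.augment_train(pc, cfg)
    probe = np.random.default_rng(5)
    probe.uniform(0.0, 0.0)                    # dropout draw
    s = probe.uniform(0.8, 1.25)
    t = probe.uniform(-0.1, 0.1, size=3)
    np.testing.assert_allclose(out.coords, pc.coords * s + t, rtol=1e-12)


def test_augment_max_dropout_replaces_exact_count(rng):
    pc = make_cloud(rng, 1024)
    cfg = tf.AugmentConfig(dropout_range=(0.875, 0.875), seed=6)
    out = tf.augment_train(pc, cfg)
    assert len(out) == 1024                    # count never changes
    first = out.coords[0]
    n_equal = int(np.sum(np.all(out.coords == first, axis=1)))
    assert n_equal >= int(np.floor(0.875 * 1024))   # 896 replaced (+ point 0)


def test_augment_draw_ranges(rng):
    cfg = tf.AugmentConfig(seed=7)
    gen = np.random.default_rng(7)
    ratios, scales = [], []
    for _ in range(1000):
        ratios.append(gen.uniform(*cfg.dropout_range))
        gen.choice(100, size=int(np.floor(ratios[-1] * 100)), replace=False)
        scales.append(gen.uniform(*cfg.scale_range))
        gen.uniform(-0.1, 0.1, size=3)
    assert 0.0 <= min(ratios) and max(ratios) <= 0.875
    assert 0.8 <= min(scales) and max(scales) <= 1.25


def test_augment_batch_matches_per_cloud_semantics(rng):
    batch = rng.standard_normal((4, 32, 3))
    cfg = tf.AugmentConfig()
    out = tf.augment_batch(batch, cfg, np.random.default_rng(0))
    assert out.shape == batch.shape
    out2 = tf.augment_batch(batch, cfg, np.random.default_rng(0))
    np.testing.assert_array_equal(out, out2)
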