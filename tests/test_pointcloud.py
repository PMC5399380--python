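"""Point-cloud construction, subsampling, DBSCAN, main-cluster extraction."""

import numpy as np
import pytest

from lumenfill import (
    PointCloud,
    cluster_points,
    default_eps_um,
    extract_main_cluster,
    mask_to_points,
    subsample,
)
from lumenfill.pointcloud import ClusterLabeling
from lumenfill.segmentation import BinaryMask


def brute_force_dbscan(points, eps, min_pts):
    """O(n²) DBSCAN oracle with index-order cluster seeding.

    Core points have >= min_pts neighbours (self included) within eps;
    each unlabelled core point in index order seeds a new cluster that
    expands over density-reachable points; border points therefore join
    the cluster whose first core point has the lowest index.
    """
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    neigh = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neigh])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neigh[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    return labels


def canon(labels):
    """Relabel clusters by first appearance so labellings compare equal."""
    mapping, out = {}, []
    for lab in labels:
        if lab == -1:
            out.append(-1)
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return out


def cloud_of(points):
    return PointCloud(points=np.asarray(points, float), source_pitch=(1.0, 1.0, 1.0))


class TestMaskToPoints:
    def test_voxel_centre_convention(self):
        mask = np.zeros((4, 4, 8), dtype=bool)
        mask[1, 2, 3] = True
        cloud = mask_to_points(BinaryMask(mask=mask, threshold_used=0), (2.0, 0.5, 0.5))
        np.testing.assert_allclose(cloud.points[0], [1.75, 1.25, 3.0])

    def test_full_cube_unit_pitch(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        cloud = mask_to_points(BinaryMask(mask=mask, threshold_used=0), (1, 1, 1))
        assert len(cloud) == 8
        assert cloud.points.min() == 0.5 and cloud.points.max() == 1.5

    def test_pitch_linearity_in_z(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[2, 1, 1] = True
        p1 = mask_to_points(BinaryMask(mask=mask, threshold_used=0), (1, 1, 1)).points[0]
        p2 = mask_to_points(BinaryMask(mask=mask, threshold_used=0), (2, 1, 1)).points[0]
        assert p2[2] == 2 * p1[2] and p2[0] == p1[0] and p2[1] == p1[1]

    def test_volume_faithful(self, hollow_small, run_config):
        from lumenfill import binarize, build_profile, compute_threshold

        stack, _ = hollow_small
        mask = binarize(stack, compute_threshold(build_profile(stack)))
        cloud = mask_to_points(mask, stack.pitch)
        assert len(cloud) * stack.voxel_volume_um3 == pytest.approx(
            mask.mask.sum() * stack.voxel_volume_um3)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mask_to_points(BinaryMask(mask=np.zeros((2, 2, 2), bool), threshold_used=0),
                           (1, 1, 1))


class TestSubsample:
    def test_identity_when_small(self, rng):
        cloud = cloud_of(rng.random((10, 3)))
        assert subsample(cloud, 20, seed=1) is cloud

    def test_exact_size_and_membership(self, rng):
        pts = rng.random((5000, 3))
        sub = subsample(cloud_of(pts), 500, seed=1)
        assert len(sub) == 500
        # every kept point is one of the originals
        assert {tuple(p) for p in sub.points} <= {tuple(p) for p in pts}

    def test_deterministic(self, rng):
        cloud = cloud_of(rng.random((1000, 3)))
        a = subsample(cloud, 100, seed=9).points
        b = subsample(cloud, 100, seed=9).points
        np.testing.assert_array_equal(a, b)


class TestDBSCAN:
    def test_two_separated_balls(self, rng):
        big = rng.normal(0, 2, (200, 3))
        small = rng.normal(0, 2, (20, 3)) + [100, 0, 0]
        labeling = cluster_points(cloud_of(np.vstack([big, small])), eps_um=5, min_points=5)
        labs = set(labeling.labels)
        assert labs - {-1} == {0, 1}

    def test_single_cluster_when_eps_spans_cloud(self, rng):
        cloud = cloud_of(rng.random((50, 3)))
        labeling = cluster_points(cloud, eps_um=10.0, min_points=3)
        assert set(labeling.labels) == {0}

    def test_matches_brute_force_oracle(self, rng):
        """sklearn-backed labelling equals the O(n²) oracle on random clouds."""
        for trial in range(50):
            pts = rng.uniform(0, 20, (200, 3))
            eps = float(rng.uniform(1.0, 4.0))
            min_pts = int(rng.integers(2, 8))
            got = cluster_points(cloud_of(pts), eps_um=eps, min_points=min_pts).labels
            want = brute_force_dbscan(pts, eps, min_pts)
            assert canon(got) == canon(want), f"trial {trial}"

    def test_permutation_invariant_partition(self, rng):
        pts = rng.uniform(0, 10, (150, 3))
        perm = rng.permutation(150)
        l1 = cluster_points(cloud_of(pts), 2.0, 4).labels
        l2 = cluster_points(cloud_of(pts[perm]), 2.0, 4).labels
        # same partition: build the set of frozensets of point tuples per cluster
        def parts(points, labels):
            out = {}
            for p, lab in zip(points, labels):
                out.setdefault(lab, set()).add(tuple(np.round(p, 9)))
            noise = out.pop(-1, set())
            return set(map(frozenset, out.values())), noise
        c1, n1 = parts(pts, l1)
        c2, n2 = parts(pts[perm], l2)
        # core memberships are order-free; border ties may swap between
        # clusters, so compare cluster count and noise set
        assert len(c1) == len(c2) and n1 == n2


class TestMainCluster:
    def test_largest_cluster_wins(self, rng):
        big = rng.normal(0, 2, (200, 3))
        small = rng.normal(0, 2, (20, 3)) + [100, 0, 0]
        cloud = cloud_of(np.vstack([big, small]))
        labeling = cluster_points(cloud, eps_um=5, min_points=5)
        main = extract_main_cluster(cloud, labeling)
        assert len(main) == 200

    def test_tie_breaks_to_lowest_label(self):
        cloud = cloud_of(np.arange(12).reshape(4, 3))
        labeling = ClusterLabeling(labels=np.array([1, 1, 0, 0]), eps_um=1, min_points=1)
        main = extract_main_cluster(cloud, labeling)
        np.testing.assert_array_equal(main.points, cloud.points[2:])

    def test_all_noise_raises(self):
        cloud = cloud_of(np.arange(9).reshape(3, 3))
        labeling = ClusterLabeling(labels=np.array([-1, -1, -1]), eps_um=1, min_points=9)
        with pytest.raises(ValueError, match="noise"):
            extract_main_cluster(cloud, labeling)

    def test_salt_noise_excluded(self, hollow_small, rng):
        """Isolated far-away voxels injected into the mask are >= 99% rejected."""
        from lumenfill import binarize, build_profile, compute_threshold

        stack, _ = hollow_small
        mask = binarize(stack, compute_threshold(build_profile(stack)))
        noise_idx = []
        nz, ny, nx = mask.mask.shape
        dz_, dy_, dx_ = stack.pitch
        centre = np.array([nz * dz_, ny * dy_, nx * dx_]) / 2
        while len(noise_idx) < 100:
            z, y, x = rng.integers(0, nz), rng.integers(0, ny), rng.integers(0, nx)
            pos = np.array([(z + .5) * dz_, (y + .5) * dy_, (x + .5) * dx_])
            # > 19 um from centre: at least 5 um clear of the 14 um spheroid,
            # beyond the default eps of 4 um
            if not mask.mask[z, y, x] and np.linalg.norm(pos - centre) > 19.0:
                mask.mask[z, y, x] = True
                noise_idx.append((z, y, x))
        cloud = mask_to_points(mask, stack.pitch)
        eps = default_eps_um(stack.pitch)
        labeling = cluster_points(cloud, eps_um=eps, min_points=10)
        main = extract_main_cluster(cloud, labeling)
        kept = {tuple(p) for p in np.round(main.points, 6)}
        dz, dy, dx = stack.pitch
        injected = {(round((x + .5) * dx, 6), round((y + .5) * dy, 6), round((z + .5) * dz, 6))
                    for z, y, x in noise_idx}
        assert len(kept & injected) <= 1  # >= 99% of 100 injected voxels excluded


def test_default_eps_scales_with_max_pitch():
    assert default_eps_um((2.0, 0.5, 0.5)) == 4.0
    assert default_eps_um((1.0, 1.0, 1.0), factor=3.0) == 3.0
    with pytest.raises(ValueError):
        default_eps_um((1, 1, 1), factor=0.0)
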