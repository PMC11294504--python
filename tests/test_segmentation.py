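import itertools

import numpy as np
import pytest

from cardioreorient.core_volume import Volume3D
from cardioreorient.segmentation import (
    SegmentationFailure,
    fcm_cluster,
    fcm_objective,
    kmeans_cluster,
    kmeans_objective,
    mask_to_points,
    mrs_sample,
    pso_fcm_segment,
    pso_optimize,
)


class TestKMeans:
    def test_k1_centroid_is_mean(self):
        vals = np.array([1.0, 2.0, 7.5, 9.0])
        res = kmeans_cluster(vals, k=1)
        assert res.centroids[0] == pytest.approx(vals.mean())

    def test_separated_masses(self):
        vals = np.concatenate([np.zeros(20), np.full(20, 100.0)]) + np.tile([0, 0.1], 20)
        res = kmeans_cluster(vals, k=2, seed=1)
        np.testing.assert_allclose(sorted(res.centroids), [0.05, 100.05], atol=1e-9)

    def test_matches_exhaustive_best_partition(self):
        # for 1-D data the optimal 2-means partition is contiguous in sorted order
        rng = np.random.default_rng(7)
        vals = np.sort(rng.uniform(0, 10, 12))
        best = np.inf
        for cut in range(1, 12):
            left, right = vals[:cut], vals[cut:]
            obj = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
            best = min(best, obj)
        res = kmeans_cluster(vals, k=2, seed=0)
        assert res.objective == pytest.approx(best, abs=1e-9)

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(8)
        res = kmeans_cluster(rng.uniform(0, 1, 200), k=3, seed=2)
        assert np.all(np.diff(res.objective_trace) <= 1e-12)

    def test_more_clusters_than_distinct_values(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.array([1.0, 1.0, 1.0, 2.0]), k=3)

    def test_matches_sklearn_reference(self):
        # independent reference implementation on a well-separated sample
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(14)
        vals = np.concatenate([rng.normal(1, 0.2, 50), rng.normal(5, 0.2, 50), rng.normal(9, 0.2, 50)])
        ours = kmeans_cluster(vals, k=3, seed=0)
        ref = KMeans(n_clusters=3, n_init=10, random_state=0).fit(vals[:, None])
        np.testing.assert_allclose(ours.centroids, sorted(ref.cluster_centers_.ravel()), atol=1e-6)
        assert ours.objective == pytest.approx(ref.inertia_, rel=1e-9)


class TestFCM:
    def test_membership_singularity_at_centroid(self):
        vals = np.array([0.0, 1.0, 5.0, 10.0])
        res = fcm_cluster(vals, k=2, seed=0)
        # a value exactly at a centroid gets membership 1 there
        from cardioreorient.segmentation import _fcm_memberships

        u = _fcm_memberships(np.array([res.centroids[0]]), res.centroids, 2.0)
        np.testing.assert_allclose(u, [[1.0, 0.0]])

    def test_symmetric_midpoint_membership(self):
        from cardioreorient.segmentation import _fcm_memberships

        u = _fcm_memberships(np.array([0.0]), np.array([-3.0, 3.0]), 2.0)
        np.testing.assert_allclose(u, [[0.5, 0.5]])

    def test_rows_normalized_every_iteration(self):
        rng = np.random.default_rng(9)
        res = fcm_cluster(rng.uniform(0, 5, 300), k=3, seed=3)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(10)
        res = fcm_cluster(rng.uniform(0, 5, 300), k=3, seed=4)
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_reaches_multistart_optimum(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 10, 10)
        best = min(fcm_cluster(vals, k=2, m=2.0, seed=s).objective for s in range(100))
        res = fcm_cluster(vals, k=2, m=2.0, seed=123)
        assert res.objective <= best + 1e-6

    def test_invalid_fuzzifier(self):
        with pytest.raises(ValueError):
            fcm_cluster(np.arange(5.0), k=2, m=1.0)


class TestPSO:
    def test_convex_quadratic_minimum(self):
        target = 3.7
        got = pso_optimize(lambda c: float((c[0] - target) ** 2), k=1, bounds=(0.0, 10.0), seed=0)
        assert abs(got[0] - target) < 1e-3

    def test_deterministic_for_fixed_seed(self):
        obj = lambda c: float(((c - np.array([1.0, 5.0, 9.0])) ** 2).sum())
        a = pso_optimize(obj, k=3, bounds=(0.0, 10.0), seed=5)
        b = pso_optimize(obj, k=3, bounds=(0.0, 10.0), seed=5)
        np.testing.assert_array_equal(a, b)

    def test_pso_seeding_beats_plain_fcm(self):
        # paired trials on a 3-cluster sample: PSO-seeded FCM should match or
        # beat plain FCM's final objective in at least 90% of seeds
        rng = np.random.default_rng(12)
        vals = np.concatenate([
            rng.normal(0, 0.3, 40),
            rng.normal(5, 0.3, 40),
            rng.normal(10, 0.3, 40),
        ])
        wins = 0
        trials = 50
        for s in range(trials):
            plain = fcm_cluster(vals, k=3, seed=s).objective
            init = pso_optimize(lambda c: fcm_objective(vals, c), k=3, bounds=(vals.min(), vals.max()),
                                swarm_size=10, iters=30, seed=s)
            seeded = fcm_cluster(vals, k=3, seed=s, init_centroids=init).objective
            if seeded <= plain + 1e-9:
                wins += 1
        assert wins >= 0.9 * trials

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            pso_optimize(lambda c: 0.0, k=1, bounds=(0.0, np.inf))


class TestPSOFCMSegment:
    def test_dice_against_truth_shell(self, segmented_clean, divided_clean):
        from conftest import resample_truth_mask

        division, mask, truth = segmented_clean
        truth_div = resample_truth_mask(truth.shell_mask, division.box, division.cropped.shape)
        inter = (mask.mask & truth_div).sum()
        dice = 2.0 * inter / (mask.mask.sum() + truth_div.sum())
        assert dice >= 0.80

    def test_single_connected_component(self, segmented_clean):
        from scipy import ndimage

        _, mask, _ = segmented_clean
        _, n = ndimage.label(mask.mask, structure=np.ones((3, 3, 3), dtype=int))
        assert n == 1

    def test_constant_volume_fails(self):
        vol = Volume3D(np.full((16, 16, 16), 4.0), (1.0, 1.0, 1.0))
        with pytest.raises(SegmentationFailure):
            pso_fcm_segment(vol)

    def test_bit_reproducible(self):
        rng = np.random.default_rng(13)
        data = rng.uniform(0, 10, (20, 20, 16))
        vol = Volume3D(data, (1.0, 1.0, 1.0))
        m1 = pso_fcm_segment(vol, seed=7)
        m2 = pso_fcm_segment(vol, seed=7)
        np.testing.assert_array_equal(m1.mask, m2.mask)


class TestMRS:
    def _shell_volume(self, r=10.0, shape=(40, 40, 40)):
        idx = np.indices(shape).astype(float)
        c = (np.asarray(shape) - 1) / 2.0
        rad = np.sqrt(((idx - c[:, None, None, None]) ** 2).sum(axis=0))
        return Volume3D((np.abs(rad - r) <= 1.0).astype(float) * 5.0, (1.0, 1.0, 1.0))

    def test_spherical_shell_radii(self):
        vol = self._shell_volume(r=10.0)
        pc = mrs_sample(vol, center=(0.0, 0.0, 0.0), n_directions=100)
        radii = np.linalg.norm(pc.points, axis=1)
        assert np.all(radii >= 9.0 - 1e-9) and np.all(radii <= 11.0 + 1e-9)

    def test_axis_rays_on_axis_aligned_shell(self):
        vol = self._shell_volume(r=10.0)
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
        pc = mrs_sample(vol, center=(0.0, 0.0, 0.0), directions=dirs)
        assert len(pc) == 6
        radii = np.linalg.norm(pc.points, axis=1)
        np.testing.assert_allclose(radii, 10.0, atol=1.0)

    def test_center_outside_grid_rejected(self):
        vol = self._shell_volume()
        with pytest.raises(ValueError, match="outside"):
            mrs_sample(vol, center=(100.0, 0.0, 0.0), n_directions=10)

    def test_constant_volume_flagged(self):
        vol = Volume3D(np.full((16, 16, 16), 2.0), (1.0, 1.0, 1.0))
        with pytest.warns(UserWarning, match="low-contrast"):
            pc = mrs_sample(vol, center=(0.0, 0.0, 0.0), n_directions=20)
        assert np.all(np.isfinite(pc.points))


class TestMaskToPoints:
    def test_single_center_voxel_maps_to_origin(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[4, 4, 4] = True
        pc = mask_to_points(mask, (2.0, 2.0, 2.0))
        np.testing.assert_allclose(pc.points, [[0.0, 0.0, 0.0]])

    def test_symmetric_voxels_sum_to_zero(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[2, 4, 4] = mask[6, 4, 4] = True
        pc = mask_to_points(mask, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(pc.points.sum(axis=0), 0.0, atol=1e-12)

    def test_point_count_matches_mask(self, segmented_clean):
        division, mask, _ = segmented_clean
        pc = mask_to_points(mask, division.cropped.spacing)
        assert len(pc) == mask.n_voxels

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            mask_to_points(np.zeros((4, 4, 4), dtype=bool), (1.0, 1.0, 1.0))
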