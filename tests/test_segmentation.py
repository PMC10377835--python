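"""Run-length window features and rough K-means clustering."""

import numpy as np
import pytest

from oraldx.preprocess import preprocess_image
from oraldx.segmentation import (
    EmptyCentersError,
    RoughApproximation,
    RoughCluster,
    assign_rough_memberships,
    glrlm_matrix,
    glrlm_window_features,
    mask_from_clusters,
    quantize,
    rough_boundary_distance,
    rough_kmeans,
    rough_limits,
    segment_image,
    update_rough_centers,
)


class TestGlrlm:
    def test_constant_window_run_percentage(self):
        img = np.full((4, 4), 99, dtype=np.uint8)
        fmap = glrlm_window_features(img)
        # four horizontal runs of length 4 over 16 pixels
        assert fmap.features[0, 0, 4] == pytest.approx(4 / 16)

    def test_checkerboard_short_run_emphasis(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        img[::2, 1::2] = 255
        img[1::2, ::2] = 255
        fmap = glrlm_window_features(img)
        # every run has length 1
        assert fmap.features[0, 0, 0] == pytest.approx(1.0)
        assert fmap.features[0, 0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_run_lengths_conserve_pixel_count(self, seed):
        rng = np.random.default_rng(seed)
        q = quantize(rng.integers(0, 256, size=(4, 4), dtype=np.uint8), 8)
        mat = glrlm_matrix(q, 8)
        lengths = np.arange(1, mat.shape[1] + 1)
        assert (mat * lengths[None, :]).sum() == 16

    def test_window_features_match_per_window_matrix_oracle(self, rng):
        img = rng.integers(0, 256, size=(12, 8), dtype=np.uint8)
        fmap = glrlm_window_features(img, window=4, levels=8)
        q = quantize(img, 8)
        for wy in range(3):
            for wx in range(2):
                win = q[wy * 4 : wy * 4 + 4, wx * 4 : wx * 4 + 4]
                mat = glrlm_matrix(win, 8).astype(float)
                nr = mat.sum()
                lengths = np.arange(1, 5, dtype=float)
                expect = [
                    (mat / lengths[None, :] ** 2).sum() / nr,
                    (mat * lengths[None, :] ** 2).sum() / nr,
                    (mat.sum(axis=1) ** 2).sum() / nr,
                    (mat.sum(axis=0) ** 2).sum() / nr,
                    nr / 16,
                ]
                np.testing.assert_allclose(fmap.features[wy, wx], expect, rtol=1e-12)

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            glrlm_window_features(np.zeros((3, 3), dtype=np.uint8))


class TestRoughApproximation:
    def test_lower_must_be_subset_of_upper(self):
        with pytest.raises(ValueError):
            RoughApproximation(lower={1, 2}, upper={1})

    def test_limits_and_boundary_distance(self):
        approx = RoughApproximation(lower={0}, upper={0, 1, 2})
        values = {0: 1.0, 1: 2.0, 2: 6.0}
        lo, up = rough_limits(approx, values)
        assert lo == pytest.approx(1.0)
        assert up == pytest.approx(3.0)
        assert rough_boundary_distance(approx, values) == pytest.approx(2.0)


class TestAssignMemberships:
    def test_zero_threshold_gives_hard_assignment(self):
        centers = np.array([[0.0, 0.0], [5.0, 5.0]])
        rec = assign_rough_memberships(np.array([1.0, 1.0]), centers, 0.0)
        assert rec.nearest == 0 and rec.in_lower and rec.candidates == ()

    def test_equidistant_point_joins_both_uppers(self):
        centers = np.array([[0.0, 0.0], [2.0, 0.0]])
        rec = assign_rough_memberships(np.array([1.0, 0.0]), centers, 0.5)
        assert not rec.in_lower and set(rec.upper_of) == {0, 1}

    def test_matches_brute_force_rule(self, rng):
        centers = rng.normal(size=(2, 3))
        for _ in range(5):
            v = rng.normal(size=3)
            rec = assign_rough_memberships(v, centers, 0.5)
            d = np.linalg.norm(centers - v, axis=1)
            i = int(np.argmin(d))
            t = {j for j in range(2) if j != i and d[j] - d[i] <= 0.5}
            assert rec.nearest == i
            assert set(rec.candidates) == t
            assert rec.in_lower == (not t)

    def test_empty_centers_raise(self):
        with pytest.raises(EmptyCentersError):
            assign_rough_memberships(np.zeros(2), np.empty((0, 2)), 0.1)


class TestCenterUpdate:
    def _cluster(self, lower, upper, w_lower=0.7):
        return RoughCluster(
            center=np.zeros(2),
            approx=RoughApproximation(lower=lower, upper=upper),
            w_lower=w_lower,
        )

    def test_empty_boundary_full_weight_is_centroid(self):
        feats = np.array([[0.0, 0.0], [2.0, 2.0], [4.0, 4.0]])
        c = self._cluster({0, 1, 2}, {0, 1, 2}, w_lower=1.0)
        np.testing.assert_allclose(update_rough_centers([c], feats)[0], [2.0, 2.0])

    def test_weighted_lower_boundary_mean(self):
        feats = np.array([[0.0, 0.0], [2.0, 2.0]])
        c = self._cluster({0}, {0, 1}, w_lower=0.7)
        np.testing.assert_allclose(update_rough_centers([c], feats)[0], [0.6, 0.6])

    def test_duplicate_points_behave_like_weighted_copy(self):
        feats = np.array([[1.0, 3.0], [1.0, 3.0], [5.0, 7.0]])
        c_dup = self._cluster({0, 1, 2}, {0, 1, 2}, w_lower=1.0)
        expected = (2 * np.array([1.0, 3.0]) + np.array([5.0, 7.0])) / 3
        np.testing.assert_allclose(update_rough_centers([c_dup], feats)[0], expected)

    def test_weights_sum_to_one_exactly(self):
        c = self._cluster({0}, {0}, w_lower=0.7)
        assert c.w_lower + c.w_upper == 1.0


def _lloyd_oracle(features, centers, max_iter=200):
    """Plain K-means to convergence from given centers (test oracle)."""
    for _ in range(max_iter):
        d = np.linalg.norm(features[:, None, :] - centers[None, :, :], axis=2)
        labels = d.argmin(axis=1)
        new = np.array(
            [
                features[labels == j].mean(axis=0) if np.any(labels == j) else centers[j]
                for j in range(len(centers))
            ]
        )
        if np.allclose(new, centers, atol=1e-12):
            break
        centers = new
    return labels


class TestRoughKMeans:
    @pytest.mark.parametrize("seed", range(20))
    def test_zero_threshold_equals_classical_kmeans(self, seed):
        rng = np.random.default_rng(seed)
        blob1 = rng.normal(0.0, 1.0, size=(15, 2))
        blob2 = rng.normal(6.0, 1.0, size=(15, 2))
        feats = np.vstack([blob1, blob2])
        clusters = rough_kmeans(feats, k=2, threshold=0.0, seed=seed)
        init = feats[np.random.default_rng(seed).choice(len(feats), 2, replace=False)]
        oracle_labels = _lloyd_oracle(feats, init.copy())
        rough_labels = np.full(len(feats), -1)
        for j, cl in enumerate(clusters):
            for i in cl.approx.lower:
                rough_labels[i] = j
        assert np.all(rough_labels >= 0), "threshold 0 must give all-lower members"
        # same partition (allow cluster index swap)
        same = np.array_equal(rough_labels, oracle_labels)
        swapped = np.array_equal(1 - rough_labels, oracle_labels)
        assert same or swapped

    def test_k1_returns_global_centroid_all_lower(self, rng):
        feats = rng.normal(size=(10, 3))
        (cluster,) = rough_kmeans(feats, k=1, seed=0)
        np.testing.assert_allclose(cluster.center, feats.mean(axis=0), atol=1e-5)
        assert cluster.approx.lower == set(range(10))

    def test_huge_threshold_makes_everything_boundary(self, rng):
        feats = rng.normal(size=(12, 2))
        clusters = rough_kmeans(feats, k=2, threshold=1e9, seed=0)
        for cl in clusters:
            assert cl.approx.lower == set()
            assert cl.approx.upper == set(range(12))

    @pytest.mark.parametrize("seed", range(5))
    def test_membership_invariants_hold(self, seed, rng):
        feats = np.random.default_rng(seed).normal(size=(30, 4))
        clusters = rough_kmeans(feats, k=3, seed=seed)
        upper_count = np.zeros(30, dtype=int)
        lower_count = np.zeros(30, dtype=int)
        for cl in clusters:
            for i in cl.approx.upper:
                upper_count[i] += 1
            for i in cl.approx.lower:
                lower_count[i] += 1
        assert np.all(upper_count >= 1), "every item must join >= 1 upper set"
        assert np.all(lower_count <= 1), "lower membership must be exclusive"
        # lower members belong to exactly their own cluster's upper set
        for cl in clusters:
            for i in cl.approx.lower:
                assert upper_count[i] == 1

    def test_bad_k_rejected(self, rng):
        feats = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            rough_kmeans(feats, k=0)
        with pytest.raises(ValueError):
            rough_kmeans(feats, k=6)


class TestMaskExport:
    def test_textured_ellipse_recovered(self, textured_ellipse):
        img, gt, _ = textured_ellipse
        pre = preprocess_image(img)
        mask = segment_image(pre, seed=3).astype(bool)
        iou = (mask & gt).sum() / (mask | gt).sum()
        assert iou >= 0.7

    def test_constant_image_yields_single_label(self):
        img = np.full((64, 64), 120, dtype=np.uint8)
        mask = segment_image(img, seed=0)
        assert len(np.unique(mask)) == 1

    def test_mask_contract_binary_and_full_size(self, textured_ellipse):
        img, _, _ = textured_ellipse
        mask = segment_image(img, seed=0)
        assert mask.shape == img.shape
        assert set(np.unique(mask)) <= {0, 1}

    def test_requires_two_clusters(self, rng):
        feats = rng.normal(size=(16, 2))
        clusters = rough_kmeans(feats, k=3, seed=0)
        from oraldx.segmentation import WindowFeatureMap

        fmap = WindowFeatureMap(
            features=feats.reshape(4, 4, 2),
            variance=np.ones((4, 4)),
            window=4,
            levels=8,
        )
        with pytest.raises(ValueError):
            mask_from_clusters(clusters, fmap, (16, 16))
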