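"""Alignment and segmentation: Procrustes recovery, color filters, partitions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhizocloud import (
    ColorPointCloud,
    SimilarityTransform,
    apply_transform,
    build_scaffold_geometry,
    default_color_rules,
    estimate_similarity_transform,
    filter_blue_noise,
    remove_scaffold_points,
    rgb_to_cielab,
    segment_root_cloud,
    statistical_outlier_filter,
)
from rhizocloud.synthroot import evaluate_segmentation


class TestScaffoldGeometry:
    def test_default_layer_count(self, geometry):
        assert geometry.n_layers == 10
        np.testing.assert_allclose(geometry.layer_depths, np.arange(10) * 6.0)

    def test_interior_crossings_8x8(self, geometry):
        # 36-in side at 4-in pitch → 8 interior lines per direction per layer
        assert geometry.crossings_per_side == 8
        assert geometry.layer_crossings(0).shape == (64, 3)

    def test_crossing_coordinates(self, geometry):
        xs = sorted(set(geometry.layer_crossings(3)[:, 0]))
        np.testing.assert_allclose(xs, [4, 8, 12, 16, 20, 24, 28, 32])
        assert (geometry.layer_crossings(3)[:, 2] == 18.0).all()

    def test_bad_pitch_rejected(self):
        with pytest.raises(ValueError, match="pitch"):
            build_scaffold_geometry(side=36.0, pitch=5.0)


def _random_transform(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
    return SimilarityTransform(
        float(rng.uniform(0.5, 3.0)), R, rng.uniform(-10, 10, 3)
    )


class TestProcrustes:
    def test_identity_recovered(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 3))
        T = estimate_similarity_transform(pts, pts)
        assert T.scale == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, 0, atol=1e-12)

    def test_known_transform_recovered(self):
        # scale 2, 90° about z, translation (1,2,3): estimator must map
        # targets exactly onto controls
        rng = np.random.default_rng(1)
        targets = rng.normal(size=(8, 3))
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        T_true = SimilarityTransform(2.0, Rz, np.array([1.0, 2.0, 3.0]))
        controls = T_true.apply(targets)
        T = estimate_similarity_transform(targets, controls)
        np.testing.assert_allclose(T.apply(targets), controls, atol=1e-9)
        assert T.scale == pytest.approx(2.0, abs=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_transform_recovery_property(self, seed):
        rng = np.random.default_rng(seed)
        targets = rng.normal(size=(8, 3))
        T_true = _random_transform(rng)
        controls = T_true.apply(targets)
        T = estimate_similarity_transform(targets, controls)
        assert np.abs(T.apply(targets) - controls).max() < 1e-9

    def test_jittered_targets_bounded_residual(self):
        sigma = 0.05
        rng = np.random.default_rng(42)
        rms = []
        for _ in range(50):
            targets = rng.uniform(0, 36, (8, 3))
            T_true = _random_transform(rng)
            controls = T_true.apply(targets)
            noisy = targets + rng.normal(0, sigma, targets.shape)
            T = estimate_similarity_transform(noisy, controls)
            resid = T.apply(noisy) - controls
            rms.append(np.sqrt((resid**2).sum(axis=1).mean()) / T_true.scale)
        assert np.mean(rms) <= 3 * sigma

    def test_coplanar_targets_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [2, 3, 0]], float)
        with pytest.raises(ValueError, match="coplanar"):
            estimate_similarity_transform(pts, pts)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            estimate_similarity_transform(np.zeros((5, 3)), np.zeros((4, 3)))

    def test_no_reflection(self):
        # controls formed with a reflection: estimator must still return det +1
        rng = np.random.default_rng(3)
        targets = rng.normal(size=(8, 3))
        controls = targets * np.array([1, 1, -1.0])
        T = estimate_similarity_transform(targets, controls)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)


class TestApplyTransform:
    def test_identity(self, tiny_cloud):
        out = apply_transform(tiny_cloud, SimilarityTransform.identity())
        np.testing.assert_array_equal(out.coords, tiny_cloud.coords)
        assert out.frame_tag == "aligned"

    def test_inverse_round_trip(self, tiny_cloud):
        rng = np.random.default_rng(9)
        T = _random_transform(rng)
        out = apply_transform(apply_transform(tiny_cloud, T), T.inverse())
        np.testing.assert_allclose(out.coords, tiny_cloud.coords, atol=1e-9)

    def test_scale_doubles_lengths(self):
        T = SimilarityTransform(2.0, np.eye(3), np.zeros(3))
        v = T.apply(np.array([[1.0, 0.0, 0.0]]))
        assert np.linalg.norm(v) == pytest.approx(2.0)


class TestCielab:
    def test_white_point(self):
        lab = rgb_to_cielab(np.array([[255, 255, 255]]))
        assert lab[0, 0] == pytest.approx(100.0, abs=0.01)
        assert abs(lab[0, 1]) < 0.01 and abs(lab[0, 2]) < 0.01

    def test_pure_blue_b_star(self):
        lab = rgb_to_cielab(np.array([[0, 0, 255]]))
        assert lab[0, 2] == pytest.approx(-107.86, abs=0.1)

    def test_black(self):
        lab = rgb_to_cielab(np.array([[0, 0, 0]]))
        assert lab[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_cielab(np.array([[300, 0, 0]]))


class TestScaffoldRemoval:
    def test_labels_oracle(self, labeled_cloud, geometry):
        root, removed = remove_scaffold_points(labeled_cloud.cloud, geometry)
        res = evaluate_segmentation(labeled_cloud, removed, label="scaffold")
        n_scaffold = labeled_cloud.truth.class_counts["scaffold"]
        assert res["true_positive"] / n_scaffold >= 0.99  # scaffold removed
        kept = evaluate_segmentation(labeled_cloud, root, label="root")
        assert kept["true_positive"] / labeled_cloud.truth.class_counts["root"] >= 0.99

    def test_partition(self, labeled_cloud, geometry):
        root, removed = remove_scaffold_points(labeled_cloud.cloud, geometry)
        assert len(root) + len(removed) == len(labeled_cloud.cloud)

    def test_brown_point_on_line_retained(self, geometry):
        # exactly on a fishing line, but root-colored → color test fails → kept
        on_line = geometry.segments[0].mean(axis=0)
        cloud = ColorPointCloud([on_line], [[139, 90, 43]], frame_tag="aligned")
        root, removed = remove_scaffold_points(cloud, geometry)
        assert len(root) == 1 and len(removed) == 0

    def test_white_point_far_from_scaffold_retained(self, geometry):
        cloud = ColorPointCloud([[18.0, 18.0, 15.0]], [[250, 250, 250]],
                                frame_tag="aligned")
        root, removed = remove_scaffold_points(cloud, geometry)
        assert len(root) == 1  # position test fails; outlier-filter work

    def test_bad_tube_radius(self, tiny_cloud, geometry):
        aligned = ColorPointCloud(tiny_cloud.coords, tiny_cloud.colors, "aligned")
        with pytest.raises(ValueError, match="tube_radius"):
            remove_scaffold_points(aligned, geometry, tube_radius=0.0)


class TestBlueFilter:
    def test_removes_blue_keeps_brown(self):
        cloud = ColorPointCloud(
            [[0, 0, 0], [1, 1, 1]], [[0, 0, 255], [139, 90, 43]], "aligned"
        )
        out = filter_blue_noise(cloud)
        assert len(out) == 1
        assert out.colors[0].tolist() == [139, 90, 43]

    def test_idempotent(self, labeled_cloud):
        once = filter_blue_noise(labeled_cloud.cloud)
        twice = filter_blue_noise(once)
        assert len(once) == len(twice)
        np.testing.assert_array_equal(once.coords, twice.coords)

    def test_minus_infinity_is_identity(self, tiny_cloud):
        out = filter_blue_noise(tiny_cloud, b_min=-np.inf)
        assert len(out) == len(tiny_cloud)


class TestOutlierFilter:
    def test_far_point_removed(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.uniform(0, 5, (500, 3)), [[100.0, 100.0, 100.0]]])
        cloud = ColorPointCloud(pts, np.full((501, 3), 100))
        out = statistical_outlier_filter(cloud)
        assert len(out) == 500
        assert out.coords.max() < 50

    def test_uniform_cube_untouched_at_high_sigma(self):
        rng = np.random.default_rng(1)
        cloud = ColorPointCloud(rng.uniform(0, 5, (500, 3)), np.full((500, 3), 100))
        out = statistical_outlier_filter(cloud, n_sigma=10.0)
        assert len(out) == 500

    def test_speckle_mostly_removed_roots_mostly_kept(self, geometry):
        # dense tube cloud + 1% distant speckle
        from rhizocloud import make_phantom

        lc = make_phantom("cylinder", length=40, radius=0.3, n_points=8000, seed=8)
        rng = np.random.default_rng(9)
        n_sp = 80
        speckle = rng.uniform([0, 0, 0], [36, 36, 60], (n_sp, 3))
        pts = np.vstack([lc.cloud.coords, speckle])
        cloud = ColorPointCloud(pts, np.full((len(pts), 3), 120))
        out = statistical_outlier_filter(cloud)
        kept = {c.tobytes() for c in out.coords}
        speckle_kept = sum(1 for s in speckle if s.tobytes() in kept)
        root_kept = sum(1 for s in lc.cloud.coords if s.tobytes() in kept)
        assert speckle_kept <= 0.05 * n_sp
        assert root_kept >= 0.99 * len(lc.cloud.coords)

    def test_too_few_points_rejected(self, tiny_cloud):
        with pytest.raises(ValueError, match="k="):
            statistical_outlier_filter(tiny_cloud, k=60)


class TestEndToEnd:
    def test_precision_recall(self, labeled_cloud, geometry):
        root, log = segment_root_cloud(labeled_cloud.cloud, geometry)
        m = evaluate_segmentation(labeled_cloud, root)
        assert m["precision"] >= 0.95
        assert m["recall"] >= 0.95
        # stage log is a partition account of the input
        assert (
            log["scaffold_removed"] + log["blue_removed"]
            + log["outliers_removed"] + log["output"]
            == log["input"]
        )
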