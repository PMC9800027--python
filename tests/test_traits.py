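"""Architecture traits: hull, PCA shape, alpha shapes, depth profiles."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from rhizocloud import (
    alpha_shape_volume,
    compute_trait_report,
    convex_hull_volume,
    depth_profiles,
    global_solidity,
    make_phantom,
    max_depth,
    pca_shape_ratios,
    root_shoot_ratio,
)

UNIT_CUBE = np.array(
    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
     [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]], float
)


def brute_force_alpha_volume(pts: np.ndarray, alpha: float) -> float:
    """Independent oracle: per-tetrahedron loop with lstsq circumcenters.

    Solves |c − vᵢ|² equalities via the plain linear system per simplex, no
    vectorization shared with the implementation under test.
    """
    tri = Delaunay(pts)
    total = 0.0
    for simplex in tri.simplices:
        v = pts[simplex]
        A = 2.0 * (v[1:] - v[0])
        b = (v[1:] ** 2).sum(axis=1) - (v[0] ** 2).sum()
        try:
            c = np.linalg.lstsq(A, b, rcond=None)[0]
        except np.linalg.LinAlgError:
            continue
        if np.linalg.matrix_rank(A) < 3:
            continue
        r = np.linalg.norm(v[0] - c)
        if r <= alpha:
            total += abs(np.linalg.det(v[1:] - v[0])) / 6.0
    return total


class TestConvexHull:
    def test_unit_cube(self):
        assert convex_hull_volume(UNIT_CUBE) == pytest.approx(1.0, abs=1e-12)

    def test_regular_tetrahedron(self):
        # edge-1 regular tetrahedron has volume √2/12
        tet = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float
        ) / np.sqrt(8)
        assert convex_hull_volume(tet) == pytest.approx(np.sqrt(2) / 12, abs=1e-12)

    def test_interior_points_irrelevant(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([UNIT_CUBE, rng.uniform(0.01, 0.99, (100, 3))])
        assert convex_hull_volume(pts) == pytest.approx(1.0, abs=1e-12)

    def test_coplanar_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(ValueError, match="degenerate"):
            convex_hull_volume(pts)


class TestPcaShape:
    def test_collinear_elongation_zero(self):
        pts = np.outer(np.linspace(0, 1, 20), [1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="collinear"):
            elongation, flatness = pca_shape_ratios(pts)
        assert elongation == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(flatness)

    def test_isotropic_gaussian_near_one(self):
        rng = np.random.default_rng(1)
        e, f = pca_shape_ratios(rng.normal(size=(100_000, 3)))
        assert 0.95 <= e <= 1.05
        assert 0.95 <= f <= 1.05

    def test_planar_disk(self):
        rng = np.random.default_rng(2)
        r = np.sqrt(rng.random(50_000))
        th = rng.uniform(0, 2 * np.pi, 50_000)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), np.zeros(50_000)])
        pts[:, 2] += rng.normal(0, 1e-6, 50_000)  # break exact degeneracy
        e, f = pca_shape_ratios(pts)
        assert e == pytest.approx(1.0, abs=0.05)
        assert f == pytest.approx(0.0, abs=0.05)


class TestMaxDepth:
    @pytest.mark.parametrize(
        "z_values, expected", [([12.0], 12.0), ([0.0, 0.0, 0.0], 0.0)]
    )
    def test_direct(self, z_values, expected):
        pts = np.array([[1.0, 1.0, z] for z in z_values])
        assert max_depth(pts) == expected

    def test_cylinder_phantom(self, cylinder_phantom):
        d = max_depth(cylinder_phantom.cloud)
        assert d == pytest.approx(50.0, abs=0.3)  # tube jitter


class TestAlphaShape:
    def test_infinite_alpha_equals_hull(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, (300, 3))
        res = alpha_shape_volume(pts, np.inf)
        assert res.volume == pytest.approx(convex_hull_volume(pts), abs=1e-9)

    def test_box_diagonal_alpha_near_hull(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 10, (300, 3))
        res = alpha_shape_volume(pts, np.sqrt(3) * 10)
        hull = convex_hull_volume(pts)
        # sliver tetrahedra with huge circumradii keep this slightly below hull
        assert 0.97 * hull <= res.volume <= hull + 1e-9

    def test_tiny_alpha_zero_volume(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 100, (50, 3))  # sparse: spacing ≫ 0.01
        assert alpha_shape_volume(pts, 0.01).volume == 0.0

    def test_monotone_in_alpha_bounded_by_hull(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            pts = rng.uniform(0, 10, (200, 3))
            hull = convex_hull_volume(pts)
            vols = [alpha_shape_volume(pts, a).volume
                    for a in (0.5, 1, 2, 4, 8, np.inf)]
            assert all(v0 <= v1 + 1e-12 for v0, v1 in zip(vols, vols[1:]))
            assert vols[-1] <= hull + 1e-9

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_matches_brute_force_oracle(self, alpha):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 6, (400, 3))
        mine = alpha_shape_volume(pts, alpha).volume
        oracle = brute_force_alpha_volume(pts, alpha)
        assert mine == pytest.approx(oracle, abs=1e-8)

    def test_two_cubes_additivity(self):
        lc = make_phantom("two_cubes", side=5.0, gap=10.0, n_points=4000, seed=7)
        pts = lc.cloud.coords
        left = pts[pts[:, 0] < pts[:, 0].mean()]
        right = pts[pts[:, 0] >= pts[:, 0].mean()]
        v_both = alpha_shape_volume(pts, 2.0).volume
        v_sep = alpha_shape_volume(left, 2.0).volume + alpha_shape_volume(right, 2.0).volume
        assert v_both == pytest.approx(v_sep, rel=0.01)

    def test_bad_alpha(self):
        with pytest.raises(ValueError, match="alpha"):
            alpha_shape_volume(UNIT_CUBE, -1.0)


class TestSolidity:
    def test_dense_cube_near_one(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 10, (5000, 3))
        assert global_solidity(pts) >= 0.9

    def test_two_cubes_much_lower(self):
        rng = np.random.default_rng(8)
        dense = global_solidity(rng.uniform(0, 10, (5000, 3)))
        lc = make_phantom("two_cubes", side=5.0, gap=15.0, n_points=5000, seed=9)
        split = global_solidity(lc.cloud.coords)
        assert split < 0.5 * dense

    def test_single_tetra_exactly_one(self):
        tet = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        assert global_solidity(tet) == pytest.approx(1.0, abs=1e-12)


class TestDepthProfiles:
    def test_uniform_cylinder_flat_biomass(self):
        rng = np.random.default_rng(10)
        n = 50_000
        pts = np.column_stack(
            [18 + rng.normal(0, 0.3, n), 18 + rng.normal(0, 0.3, n),
             rng.uniform(0, 50, n)]
        )
        prof = depth_profiles(pts)
        assert prof.biomass_density.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.abs(prof.biomass_density - 0.1) < 0.02)

    def test_top_heavy_disk(self):
        rng = np.random.default_rng(11)
        n = 20_000
        disk = np.column_stack(
            [rng.uniform(0, 36, n), rng.uniform(0, 36, n),
             rng.uniform(0, 0.5, n)]
        )
        deep = np.array([[18.0, 18.0, 40.0], [18.2, 18.0, 40.0], [18.0, 18.2, 40.0],
                         [17.8, 18.0, 39.8]])
        prof = depth_profiles(np.vstack([disk, deep]))
        assert prof.biomass_density[0] >= 0.9
        assert np.all(prof.biomass_density[2:] <= 0.02)

    def test_cone_hull_area_increases_with_depth(self):
        rng = np.random.default_rng(12)
        n = 40_000
        z = rng.uniform(0, 50, n)
        radius = 1.0 + 0.3 * z  # widening cone
        r = radius * np.sqrt(rng.random(n))
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([18 + r * np.cos(th), 18 + r * np.sin(th), z])
        prof = depth_profiles(pts)
        assert np.all(np.diff(prof.hull_area) > 0)

    def test_solidity_bins_in_unit_interval(self, labeled_cloud):
        prof = depth_profiles(labeled_cloud.points_of("root").coords)
        assert np.all(prof.solidity > 0)
        assert np.all(prof.solidity <= 1.0)


class TestRootShootRatio:
    @pytest.mark.parametrize(
        "root, shoot, expected",
        [
            (126.5, 265.3, 0.48),
            (144.9, 271.1, 0.53),
            (52.9, 44.5, 1.19),
            (22.0, 36.2, 0.61),
            (98.6, 114.8, 0.86),
            (77.6, 257.6, 0.30),
            (80.3, 98.7, 0.81),
            (10.0, 10.0, 1.00),
        ],
    )
    def test_mean_weights(self, root, shoot, expected):
        assert root_shoot_ratio(root, shoot) == expected

    def test_zero_shoot_rejected(self):
        with pytest.raises(ValueError, match="shoot"):
            root_shoot_ratio(10.0, 0.0)


class TestRigidMotionInvariance:
    def test_traits_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(13)
        pts = rng.uniform(0, 8, (600, 3))
        R = Rotation.random(random_state=14).as_matrix()
        moved = pts @ R.T + np.array([5.0, -3.0, 2.0])
        assert convex_hull_volume(moved) == pytest.approx(
            convex_hull_volume(pts), rel=1e-6
        )
        assert alpha_shape_volume(moved, 2.0).volume == pytest.approx(
            alpha_shape_volume(pts, 2.0).volume, rel=1e-4
        )
        e0, f0 = pca_shape_ratios(pts)
        e1, f1 = pca_shape_ratios(moved)
        assert e1 == pytest.approx(e0, abs=1e-6)
        assert f1 == pytest.approx(f0, abs=1e-6)


class TestTraitReport:
    def test_full_report_fields(self, cylinder_phantom):
        rep = compute_trait_report(
            cylinder_phantom.cloud, root_dry_weight=52.9, shoot_dry_weight=44.5
        )
        d = rep.to_dict()
        assert d["point_count"] == len(cylinder_phantom.cloud)
        assert d["root_shoot_ratio"] == 1.19
        assert d["max_depth_cm"] == pytest.approx(d["max_depth_in"] * 2.54)
        assert 0 <= d["solidity"] <= 1
        assert set(d["alpha_volumes_in3"]) == {"0.5", "1.0", "2.0"}
        assert sum(d["depth_profile"]["biomass_density"]) == pytest.approx(1.0)
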