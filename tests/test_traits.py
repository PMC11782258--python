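"""The ten shape descriptors against closed forms and invariance laws."""

import math

import numpy as np
import pytest

from cabbage3d import PointCloud, TraitConfig, compute_traits
from cabbage3d.errors import (DegenerateGeometryError, InsufficientPointsError,
                              ValidationError)
from cabbage3d.traits import (head_roundness, height_spread_ratio,
                              hull_volume_area, mean_leaf_inclination,
                              projection_areas, radial_dimension_difference,
                              symmetry)


class TestHeightSpreadRatio:
    def test_unit_cube(self, unit_cube):
        assert height_spread_ratio(unit_cube) == pytest.approx(1 / math.sqrt(2),
                                                               abs=1e-12)

    def test_cylinder(self, rng):
        ang = rng.uniform(0, 2 * np.pi, 4000)
        z = rng.uniform(0, 2, 4000)
        pc = PointCloud(np.column_stack([0.5 * np.cos(ang), 0.5 * np.sin(ang), z]))
        assert height_spread_ratio(pc) == pytest.approx(2.0, rel=1e-3)

    def test_flat_disc_is_zero(self, rng):
        xy = rng.normal(size=(200, 2))
        pc = PointCloud(np.column_stack([xy, np.zeros(200)]))
        assert height_spread_ratio(pc) == 0.0

    def test_vertical_line_is_degenerate(self):
        pc = PointCloud(np.column_stack([np.zeros(5), np.zeros(5), np.arange(5.0)]))
        with pytest.raises(DegenerateGeometryError):
            height_spread_ratio(pc)


class TestLeafInclination:
    @staticmethod
    def _plane(normal_angle_deg, n=5000, seed=0):
        """Dense plane whose normal is tilted by the given angle from vertical."""
        r = np.random.default_rng(seed)
        u, v = r.uniform(-1, 1, (2, n))
        a = math.radians(normal_angle_deg)
        # basis: in-plane directions for a plane with normal (sin a, 0, cos a)
        e1 = np.array([math.cos(a), 0.0, -math.sin(a)])
        e2 = np.array([0.0, 1.0, 0.0])
        return PointCloud(np.outer(u, e1) + np.outer(v, e2))

    @pytest.mark.parametrize("angle", [0.0, 45.0, 90.0])
    def test_recovers_plane_tilt(self, angle):
        pc = self._plane(angle)
        assert mean_leaf_inclination(pc, k_normals=12) == pytest.approx(angle, abs=1.0)

    def test_sparse_slab_is_an_error(self, unit_cube):
        with pytest.raises(InsufficientPointsError):
            mean_leaf_inclination(unit_cube, k_normals=12)


class TestRadialDimensionDifference:
    def test_unit_square(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        w = radial_dimension_difference(PointCloud(pts))
        assert w == pytest.approx(math.sqrt(2) - 1, abs=1e-12)

    def test_regular_hexagon(self):
        hexagon = np.array([[np.cos(a), np.sin(a), 0.0]
                            for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)])
        w = radial_dimension_difference(PointCloud(hexagon))
        assert w == pytest.approx(1.0, abs=1e-12)  # diameter 2, adjacent side 1

    def test_equilateral_triangle_is_zero(self):
        tri = np.array([[np.cos(a), np.sin(a), 0.0]
                        for a in np.linspace(0, 2 * np.pi, 3, endpoint=False)])
        assert radial_dimension_difference(PointCloud(tri)) == pytest.approx(0, abs=1e-12)

    def test_width_mode_on_rectangle(self):
        rect = np.array([[0, 0, 0], [4, 0, 0], [4, 1, 0], [0, 1, 0]], dtype=float)
        w = radial_dimension_difference(PointCloud(rect), mode="width")
        assert w == pytest.approx(math.sqrt(17) - 1, abs=1e-12)

    def test_unknown_mode(self, unit_cube):
        with pytest.raises(ValidationError):
            radial_dimension_difference(unit_cube, mode="nope")


class TestHullVolumeArea:
    def test_unit_cube(self, unit_cube):
        v, s = hull_volume_area(unit_cube)
        assert v == pytest.approx(1.0, abs=1e-12)
        assert s == pytest.approx(6.0, abs=1e-12)

    def test_regular_tetrahedron(self):
        # edge length 1; V = sqrt(2)/12, S = sqrt(3)
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                         dtype=float) / (2 * math.sqrt(2))
        v, s = hull_volume_area(PointCloud(verts))
        assert v == pytest.approx(math.sqrt(2) / 12, abs=1e-9)
        assert s == pytest.approx(math.sqrt(3), abs=1e-9)

    def test_coplanar_is_degenerate(self, rng):
        xy = rng.normal(size=(30, 2))
        pc = PointCloud(np.column_stack([xy, np.zeros(30)]))
        with pytest.raises(DegenerateGeometryError):
            hull_volume_area(pc)


class TestProjectionAreas:
    def test_unit_cube(self, unit_cube):
        assert projection_areas(unit_cube) == pytest.approx((1.0, 1.0, 1.0))

    def test_vertical_segment_warns_zero_s3(self):
        seg = np.column_stack([np.zeros(10), np.full(10, 0.5), np.linspace(0, 1, 10)])
        seg[0, 0] = 0.2  # make XZ non-degenerate
        with pytest.warns(UserWarning, match="degenerate"):
            s1, s2, s3 = projection_areas(PointCloud(seg))
        assert s3 == 0.0

    def test_translation_invariance(self, random_cloud):
        pc = random_cloud(80)
        shifted = PointCloud(pc.coords + [5.0, -3.0, 2.0])
        np.testing.assert_allclose(projection_areas(shifted), projection_areas(pc),
                                   rtol=1e-9)


class TestHeadRoundness:
    def test_regular_hexagon(self):
        hexagon = np.array([[np.cos(a), np.sin(a), 0.0]
                            for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)])
        o = head_roundness(PointCloud(hexagon))
        assert o == pytest.approx(3 * math.sqrt(3) / (2 * math.pi), abs=1e-9)

    def test_unit_square(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        assert head_roundness(PointCloud(square)) == pytest.approx(2 / math.pi,
                                                                   abs=1e-9)

    def test_dense_disc_approaches_one(self, rng):
        ang = rng.uniform(0, 2 * np.pi, 10000)
        rad = np.sqrt(rng.uniform(0, 1, 10000))
        pc = PointCloud(np.column_stack([rad * np.cos(ang), rad * np.sin(ang),
                                         np.zeros(10000)]))
        assert head_roundness(pc) >= 0.99


class TestSymmetry:
    def test_cylinder_surface_is_zero(self, rng):
        # antipodal pairs cancel the xz/yz covariances exactly, so the fitted
        # main axis is exactly the cylinder axis and every d(p, L) = r
        ang = rng.uniform(0, 2 * np.pi, 1000)
        z = rng.uniform(-5, 5, 1000)
        half = np.column_stack([np.cos(ang), np.sin(ang), z])
        pc = PointCloud(np.vstack([half, half * [-1, -1, 1]]))
        assert symmetry(pc, n_groups=5) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_slab_variance(self):
        # distances to the main axis are {1,1,3,3} in each of two slabs:
        # mu=2, sigma^2=1 (population 1/S_k normalization), M=1
        pts = []
        for z in (0.0, 10.0):
            for x in (1.0, -1.0, 3.0, -3.0):
                pts.append([x, 0.0, z])
        assert symmetry(PointCloud(np.array(pts)), n_groups=2) == pytest.approx(1.0,
                                                                                abs=1e-12)

    def test_rotation_about_axis_invariant(self, rng):
        coords = rng.normal(size=(300, 3)) * [0.5, 0.5, 3.0]
        pc = PointCloud(coords)
        ang = 1.1
        Rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                       [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        assert symmetry(PointCloud(coords @ Rz.T)) == pytest.approx(symmetry(pc),
                                                                    abs=1e-9)

    def test_sparse_slabs_skipped_with_warning(self):
        pts = np.column_stack([np.ones(6), np.zeros(6),
                               np.array([0, 0, 0, 10, 10, 10.0])])
        pts[:, 0] = [1, 2, 3, 1, 2, 3]
        with pytest.warns(UserWarning, match="slabs"):
            symmetry(PointCloud(pts), n_groups=50)


class TestComputeTraits:
    def test_dense_cube_full_vector(self, rng):
        # dense samples on the surface of the unit cube: hull quantities hit
        # the closed forms, the middle slab holds only vertical faces
        n = 4000
        face = rng.integers(0, 6, n)
        uv = rng.random((n, 2))
        pts = np.empty((n, 3))
        axis = face // 2
        side = (face % 2).astype(float)
        for i in range(n):
            rest = [j for j in range(3) if j != axis[i]]
            pts[i, axis[i]] = side[i]
            pts[i, rest] = uv[i]
        tv = compute_traits(PointCloud(pts))
        assert tv.T == pytest.approx(1 / math.sqrt(2), rel=1e-2)
        assert tv.V == pytest.approx(1.0, rel=1e-2)
        assert tv.S == pytest.approx(6.0, rel=1e-2)
        assert tv.S1 == pytest.approx(1.0, rel=1e-2)
        assert tv.O == pytest.approx(2 / math.pi, rel=1e-2)
        assert tv.theta_bar == pytest.approx(90.0, abs=2.0)  # side walls only

    def test_error_annotated_with_trait_name(self, unit_cube):
        with pytest.raises(InsufficientPointsError, match="theta_bar"):
            compute_traits(unit_cube)

    def test_recomputation_is_bit_identical(self, rng):
        coords = rng.normal(size=(500, 3)) * [1, 0.8, 1.4]
        pc = PointCloud(coords)
        cfg = TraitConfig()
        a = compute_traits(pc, cfg).as_array()
        b = compute_traits(pc, cfg).as_array()
        np.testing.assert_array_equal(a, b)


class TestTransformLaws:
    """Scale/rotation/translation behavior of every descriptor."""

    @staticmethod
    def _traits(pc):
        cfg = TraitConfig(denoise_slab=False)
        return compute_traits(pc, cfg)

    def test_scaling_and_rigid_laws(self):
        for trial in range(20):
            r = np.random.default_rng(trial)
            coords = r.normal(size=(250, 3)) * [1.5, 1.0, 0.8]
            base = self._traits(PointCloud(coords))
            s = r.uniform(0.5, 2.0)
            t = r.normal(size=3)
            scaled = self._traits(PointCloud(coords * s + t))
            for name, power in [("T", 0), ("theta_bar", 0), ("O", 0), ("W", 1),
                                ("V", 3), ("S", 2), ("S1", 2), ("S2", 2),
                                ("S3", 2), ("M", 2)]:
                expect = getattr(base, name) * s ** power
                assert getattr(scaled, name) == pytest.approx(expect, rel=1e-9), name
            ang = r.uniform(0, 2 * np.pi)
            Rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                           [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
            rot = self._traits(PointCloud(coords @ Rz.T + t))
            for name in ("T", "theta_bar", "O", "W", "V", "S", "S3", "M"):
                assert getattr(rot, name) == pytest.approx(getattr(base, name),
                                                           rel=1e-9), name
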