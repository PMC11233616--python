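"""Unit tests for the geometric primitives."""

import math

import numpy as np
import pytest

from aneumorph import SacSpec, SurfaceMesh, NeckContour, make_sac
from aneumorph import mesh_core
from aneumorph.errors import GeometryError, InputError

from conftest import random_rotation

HEMI_VOL = 2 * math.pi / 3
HEMI_AREA = 2 * math.pi


# ---------------------------------------------------------------------------
# capping & watertightness

class TestCapNeck:
    def test_hemisphere_cap_is_watertight(self):
        geom, _ = make_sac(SacSpec(resolution=(64, 32)))
        closed = mesh_core.cap_neck(geom.sac, geom.neck)
        assert mesh_core.is_watertight(closed)
        with pytest.raises(GeometryError):
            mesh_core.boundary_loop(closed)

    def test_closed_mesh_rejected(self, unit_cube):
        with pytest.raises(GeometryError, match="closed"):
            mesh_core.cap_neck(unit_cube, NeckContour(np.eye(3)))

    def test_square_neck_box_gains_four_cap_faces(self, open_box_sac):
        sac, neck = open_box_sac
        closed = mesh_core.cap_neck(sac, neck)
        assert len(closed.faces) == len(sac.faces) + 4
        assert mesh_core.is_watertight(closed)

    def test_contour_mismatch_rejected(self):
        geom, _ = make_sac(SacSpec(resolution=(32, 16)))
        shifted = NeckContour(geom.neck.points + 0.1)
        with pytest.raises(GeometryError, match="mismatch"):
            mesh_core.cap_neck(geom.sac, shifted)


# ---------------------------------------------------------------------------
# volume & area

class TestVolumeArea:
    def test_unit_cube(self, unit_cube):
        assert mesh_core.enclosed_volume(unit_cube) == pytest.approx(1.0)
        assert mesh_core.surface_area(unit_cube) == pytest.approx(6.0)

    def test_hemisphere_closed_forms(self, hemisphere_fine):
        geom, _ = hemisphere_fine
        closed = mesh_core.cap_neck(geom.sac, geom.neck)
        assert mesh_core.enclosed_volume(closed) == pytest.approx(
            HEMI_VOL, rel=5e-3)
        assert mesh_core.surface_area(geom.sac) == pytest.approx(
            HEMI_AREA, rel=5e-3)

    def test_open_mesh_rejected(self, hemisphere_coarse):
        geom, _ = hemisphere_coarse
        with pytest.raises(GeometryError, match="watertight"):
            mesh_core.enclosed_volume(geom.sac)

    @pytest.mark.parametrize("family", ["hemisphere", "half_ellipsoid"])
    def test_refinement_error_decreases_monotonically(self, family):
        spec_kw = {"family": family}
        if family == "half_ellipsoid":
            spec_kw["semi_axes"] = (1.0, 1.0, 2.0)
        errs_v, errs_a = [], []
        for res in [(16, 8), (32, 16), (64, 32), (128, 64)]:
            geom, truth = make_sac(SacSpec(resolution=res, **spec_kw))
            closed = mesh_core.cap_neck(geom.sac, geom.neck)
            errs_v.append(abs(mesh_core.enclosed_volume(closed) - truth["DV"]))
            errs_a.append(abs(mesh_core.surface_area(geom.sac) - truth["DA"]))
        assert errs_v == sorted(errs_v, reverse=True)
        assert errs_a == sorted(errs_a, reverse=True)

    def test_scaling_laws(self, unit_cube):
        for s in (0.5, 2.0, 3.0):
            scaled = SurfaceMesh(unit_cube.vertices * s, unit_cube.faces)
            assert mesh_core.enclosed_volume(scaled) == pytest.approx(s**3)
            assert mesh_core.surface_area(scaled) == pytest.approx(6 * s**2)

    def test_area_doubles_under_sqrt2_scale(self, hemisphere_coarse):
        geom, _ = hemisphere_coarse
        base = mesh_core.surface_area(geom.sac)
        scaled = SurfaceMesh(geom.sac.vertices * math.sqrt(2), geom.sac.faces)
        assert mesh_core.surface_area(scaled) == pytest.approx(2 * base)


# ---------------------------------------------------------------------------
# neck plane & ostium

class TestNeckPlane:
    def circle(self, n=64, r=1.0):
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        return np.column_stack([r * np.cos(t), r * np.sin(t), np.zeros(n)])

    def test_orientation_follows_sac_side(self):
        neck = NeckContour(self.circle())
        above = mesh_core.fit_neck_plane(neck, np.array([0, 0, 2.0]))
        below = mesh_core.fit_neck_plane(neck, np.array([0, 0, -2.0]))
        np.testing.assert_allclose(above.normal, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(below.normal, [0, 0, -1], atol=1e-12)

    def test_tilted_circle_normal(self):
        a = math.radians(30)
        R = np.array([[1, 0, 0],
                      [0, math.cos(a), -math.sin(a)],
                      [0, math.sin(a), math.cos(a)]])
        neck = NeckContour(self.circle() @ R.T)
        expected = R @ np.array([0, 0, 1.0])
        plane = mesh_core.fit_neck_plane(neck, expected * 2)
        np.testing.assert_allclose(plane.normal, expected, atol=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 5), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError, match="collinear"):
            mesh_core.fit_neck_plane(NeckContour(pts), np.ones(3))

    def test_basis_is_right_handed_orthonormal(self):
        rng = np.random.default_rng(0)
        neck = NeckContour(self.circle() @ random_rotation(rng).T + 5)
        p = mesh_core.fit_neck_plane(neck, neck.points.mean(0) + p_normal_guess(neck))
        M = np.column_stack([p.in_plane_u, p.in_plane_v, p.normal])
        np.testing.assert_allclose(M @ M.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(M) == pytest.approx(1.0)


def p_normal_guess(neck):
    pts = neck.points - neck.points.mean(0)
    _, _, vt = np.linalg.svd(pts)
    return vt[2]


class TestPolygonMetrics:
    def test_circle_area_perimeter(self):
        t = np.linspace(0, 2 * math.pi, 64, endpoint=False)
        neck = NeckContour(np.column_stack(
            [np.cos(t), np.sin(t), np.zeros(64)]))
        plane = mesh_core.fit_neck_plane(neck, np.array([0, 0, 1.0]))
        na, nc, centroid = mesh_core.polygon_metrics(neck, plane)
        assert na == pytest.approx(math.pi, rel=2e-3)
        assert nc == pytest.approx(2 * math.pi, rel=2e-3)
        np.testing.assert_allclose(centroid, [0, 0, 0], atol=1e-12)

    def test_rectangle(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [2, 1, 0], [0, 1, 0]], float)
        neck = NeckContour(pts)
        plane = mesh_core.fit_neck_plane(neck, np.array([1, 0.5, 1.0]))
        na, nc, _ = mesh_core.polygon_metrics(neck, plane)
        assert na == pytest.approx(2.0)
        assert nc == pytest.approx(6.0)

    def test_warped_circle_perimeter_exceeds_projection(self):
        t = np.linspace(0, 2 * math.pi, 128, endpoint=False)
        warped = NeckContour(np.column_stack(
            [np.cos(t), np.sin(t), 0.2 * np.sin(3 * t)]))
        plane = mesh_core.fit_neck_plane(warped, np.array([0, 0, 1.0]))
        _, nc3d, _ = mesh_core.polygon_metrics(warped, plane)
        uv = plane.to_plane_coords(warped.points)
        closed = np.vstack([uv, uv[:1]])
        nc_proj = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        assert nc3d > nc_proj


# ---------------------------------------------------------------------------
# extents

class TestMaxPairwiseDistance:
    def test_hemisphere_rim_diameter(self, hemisphere_fine):
        geom, _ = hemisphere_fine
        md, pair = mesh_core.max_pairwise_distance(geom.sac.vertices)
        assert md == pytest.approx(2.0, rel=1e-3)
        assert pair[0] < pair[1]

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            pts = rng.standard_normal((50, 3))
            md, pair = mesh_core.max_pairwise_distance(pts)
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            i, j = np.unravel_index(np.argmax(d), d.shape)
            assert md == d[i, j]
            assert pair == tuple(sorted((i, j)))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((100, 3))
        md, _ = mesh_core.max_pairwise_distance(pts)
        md_rot, _ = mesh_core.max_pairwise_distance(pts @ random_rotation(rng).T)
        assert md_rot == pytest.approx(md, abs=1e-9)

    def test_needs_two_points(self):
        with pytest.raises(InputError):
            mesh_core.max_pairwise_distance(np.zeros((1, 3)))


class TestConvexHull:
    def test_hemisphere_hull_matches_itself(self, hemisphere_fine):
        geom, _ = hemisphere_fine
        closed = mesh_core.cap_neck(geom.sac, geom.neck)
        hull = mesh_core.convex_hull_metrics(closed)
        assert hull.hull_volume == pytest.approx(HEMI_VOL, rel=5e-3)
        assert hull.hull_area == pytest.approx(3 * math.pi, rel=5e-3)
        assert hull.hull_volume >= mesh_core.enclosed_volume(closed) - 1e-12

    def test_lobulated_hull_exceeds_volume(self):
        geom, _ = make_sac(SacSpec(family="lobulated", resolution=(64, 32),
                                   undulation_amplitude=0.3))
        closed = mesh_core.cap_neck(geom.sac, geom.neck)
        hull = mesh_core.convex_hull_metrics(closed)
        assert hull.hull_volume > mesh_core.enclosed_volume(closed)

    def test_coplanar_points_rejected(self):
        flat = SurfaceMesh(
            np.column_stack([np.random.default_rng(0).random((6, 2)),
                             np.zeros(6)]),
            np.array([[0, 1, 2], [2, 3, 4], [3, 4, 5]]))
        with pytest.raises(GeometryError, match="degenerate"):
            mesh_core.convex_hull_metrics(flat)


# ---------------------------------------------------------------------------
# heights & sections

class TestHeights:
    def test_hemisphere_heights(self, hemisphere_fine):
        geom, _ = hemisphere_fine
        plane = mesh_core.fit_neck_plane(geom.neck, geom.sac.vertices.mean(0))
        assert mesh_core.max_plane_distance(geom.sac, plane) == pytest.approx(
            1.0, rel=1e-6)
        assert mesh_core.central_height(geom.sac, plane) == pytest.approx(
            1.0, rel=1e-3)

    def test_half_ellipsoid_height(self):
        geom, _ = make_sac(SacSpec(family="half_ellipsoid",
                                   semi_axes=(1, 1, 2), resolution=(64, 32)))
        plane = mesh_core.fit_neck_plane(geom.neck, geom.sac.vertices.mean(0))
        assert mesh_core.max_plane_distance(geom.sac, plane) == pytest.approx(2.0)

    def test_spherical_cap_central_height(self):
        geom, _ = make_sac(SacSpec(family="spherical_cap", radius=1.0,
                                   cap_offset=0.5, resolution=(128, 64)))
        plane = mesh_core.fit_neck_plane(geom.neck, geom.sac.vertices.mean(0))
        assert mesh_core.central_height(geom.sac, plane) == pytest.approx(
            1.5, rel=1e-3)

    def test_cph_never_exceeds_mph(self):
        rng = np.random.default_rng(5)
        from aneumorph.synthetic import random_sac_spec
        for _ in range(10):
            geom, _ = make_sac(random_sac_spec(rng, resolution=(32, 16)))
            plane = mesh_core.fit_neck_plane(
                geom.neck, geom.sac.vertices.mean(0))
            cph = mesh_core.central_height(geom.sac, plane)
            mph = mesh_core.max_plane_distance(geom.sac, plane)
            assert cph <= mph + 1e-9

    def test_rigid_tilt_leaves_mph_unchanged(self, hemisphere_coarse):
        from aneumorph.synthetic import transform_geometry
        geom, _ = hemisphere_coarse
        rng = np.random.default_rng(7)
        moved = transform_geometry(geom, random_rotation(rng), np.ones(3))
        plane = mesh_core.fit_neck_plane(moved.neck, moved.sac.vertices.mean(0))
        assert mesh_core.max_plane_distance(moved.sac, plane) == pytest.approx(
            1.0, abs=1e-6)


class TestLargestParallelSection:
    def test_hemisphere_widest_at_neck(self, hemisphere_fine):
        geom, _ = hemisphere_fine
        plane = mesh_core.fit_neck_plane(geom.neck, geom.sac.vertices.mean(0))
        closed = mesh_core.cap_neck(geom.sac, geom.neck)
        assert mesh_core.largest_parallel_section(closed, plane) == 0.0

    def test_spherical_cap_widest_at_equator(self):
        geom, _ = make_sac(SacSpec(family="spherical_cap", radius=1.0,
                                   cap_offset=0.5, resolution=(128, 64)))
        plane = mesh_core.fit_neck_plane(geom.neck, geom.sac.vertices.mean(0))
        closed = mesh_core.cap_neck(geom.sac, geom.neck)
        step = 1.5 / 199
        mdpn = mesh_core.largest_parallel_section(closed, plane, n_slices=200)
        assert abs(mdpn - 0.5) <= step

    def test_converges_when_slices_double(self):
        geom, _ = make_sac(SacSpec(family="spherical_cap", radius=1.0,
                                   cap_offset=0.4, resolution=(64, 32)))
        plane = mesh_core.fit_neck_plane(geom.neck, geom.sac.vertices.mean(0))
        closed = mesh_core.cap_neck(geom.sac, geom.neck)
        mph = mesh_core.max_plane_distance(geom.sac, plane)
        d1 = mesh_core.largest_parallel_section(closed, plane, n_slices=100)
        d2 = mesh_core.largest_parallel_section(closed, plane, n_slices=200)
        assert abs(d1 - d2) < mph / 99

    def test_cross_section_area_of_sphere_slice(self):
        geom, _ = make_sac(SacSpec(family="spherical_cap", radius=1.0,
                                   cap_offset=0.5, resolution=(128, 64)))
        closed = mesh_core.cap_neck(geom.sac, geom.neck)
        # slice through the equator: area pi r^2
        area = mesh_core.cross_section_area(
            closed, np.array([0, 0, 0.0]), np.array([0, 0, 1.0]))
        assert area == pytest.approx(math.pi, rel=5e-3)


class TestProjectionLength:
    def test_hemisphere_axes(self, hemisphere_fine):
        geom, _ = hemisphere_fine
        in_plane = mesh_core.projection_length(geom.sac, np.array([1, 0, 0.0]))
        normal = mesh_core.projection_length(geom.sac, np.array([0, 0, 1.0]))
        assert in_plane == pytest.approx(2.0, rel=1e-3)
        assert normal == pytest.approx(1.0, rel=1e-3)
        flipped = mesh_core.projection_length(geom.sac, np.array([-1, 0, 0.0]))
        assert flipped == in_plane
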