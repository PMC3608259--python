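"""Spline/surface kernel: curve evaluation, lofting, Coons patches,
revolution surfaces and watertight tessellation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dentiform.geometry import (
    BSplineCurve,
    GeometryError,
    coons_patch,
    interpolating_open_curve,
    is_closed,
    loft_sections,
    revolve_profile,
    tessellate,
)
from conftest import circle_section


def _seg(a, b):
    return BSplineCurve(np.array([a, b], dtype=float), degree=1)


class TestCurves:
    def test_linear_curve_interpolates_midpoint(self):
        c = BSplineCurve(np.array([[0, 0, 0], [2, 0, 0]]), degree=1)
        assert np.allclose(c.evaluate(0.5), [1, 0, 0])

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), degree=st.integers(1, 3),
           n_extra=st.integers(1, 5))
    def test_clamped_curves_interpolate_end_control_points(self, seed, degree,
                                                           n_extra):
        rng = np.random.default_rng(seed)
        cp = rng.normal(scale=5, size=(degree + n_extra, 3))
        c = BSplineCurve(cp, degree=degree)
        assert np.allclose(c.evaluate(0.0), cp[0], atol=1e-12)
        assert np.allclose(c.evaluate(1.0), cp[-1], atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), t=st.floats(-2, 3))
    def test_closed_curve_evaluation_is_periodic(self, seed, t):
        rng = np.random.default_rng(seed)
        c = BSplineCurve(rng.normal(scale=5, size=(7, 3)), degree=3,
                         closed=True)
        assert np.allclose(c.evaluate(t), c.evaluate(t % 1.0), atol=1e-9)

    def test_open_curve_stays_in_control_hull(self):
        rng = np.random.default_rng(3)
        cp = rng.normal(scale=4, size=(6, 3))
        c = BSplineCurve(cp, degree=3)
        pts = c.evaluate(np.linspace(0, 1, 200))
        # hull membership per coordinate bound (necessary condition)
        assert np.all(pts.min(axis=0) >= cp.min(axis=0) - 1e-9)
        assert np.all(pts.max(axis=0) <= cp.max(axis=0) + 1e-9)

    def test_octagon_closed_spline_is_nearly_circular(self):
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        c = BSplineCurve(np.c_[10 * np.cos(ang), 10 * np.sin(ang),
                               np.zeros(8)], degree=3, closed=True)
        p = c.evaluate(np.linspace(0, 1, 4000, endpoint=False))
        r = np.linalg.norm(p[:, :2], axis=1)
        # dense-sampling oracle: radial deviation from the best-fit circle
        assert np.abs(r - r.mean()).max() < 0.5
        assert np.abs(r - r.mean()).max() == pytest.approx(0.0055, abs=0.002)

    def test_parameter_outside_domain_rejected(self):
        c = BSplineCurve(np.array([[0, 0, 0], [2, 0, 0]]), degree=1)
        with pytest.raises(GeometryError):
            c.evaluate(1.5)

    def test_too_few_control_points_rejected(self):
        with pytest.raises(GeometryError):
            BSplineCurve(np.zeros((3, 3)), degree=3)


class TestLoft:
    def test_two_circles_loft_to_cylinder_area(self):
        surf = loft_sections([circle_section(3, 0), circle_section(3, 10)])
        mesh = tessellate(surf, 64, 16)
        assert mesh.area == pytest.approx(2 * np.pi * 3 * 10, rel=0.02)

    def test_cylinder_tube_topology(self):
        surf = loft_sections([circle_section(3, 0), circle_section(3, 10)])
        mesh = tessellate(surf, 64, 16)
        # open tube: 2 boundary loops, not watertight
        assert not is_closed(mesh)
        boundary_edges = (np.bincount(mesh.edges_unique_inverse) == 1).sum()
        assert boundary_edges == 2 * 64

    def test_near_point_section_gives_cone_apex(self):
        surf = loft_sections([circle_section(3, 0), circle_section(0.01, 10)])
        mesh = tessellate(surf, 64, 24)
        assert mesh.vertices[:, 2].max() == pytest.approx(10.0, abs=1e-9)

    def test_three_circle_loft_interpolates_middle_section(self):
        surf = loft_sections([circle_section(4, 0), circle_section(2, 5),
                              circle_section(1, 10)])
        mesh = tessellate(surf, 64, 48)
        sec = mesh.section(plane_origin=[0, 0, 5], plane_normal=[0, 0, 1])
        pts = np.vstack(sec.discrete)
        width = pts[:, 0].max() - pts[:, 0].min()
        assert width == pytest.approx(4.0, abs=0.05)

    def test_single_section_rejected(self):
        with pytest.raises(GeometryError):
            loft_sections([circle_section(3, 0)])

    def test_sections_auto_reorient(self):
        cw = BSplineCurve(circle_section(3, 10).control_points[::-1],
                          degree=3, closed=True)
        surf = loft_sections([circle_section(3, 0), cw])
        mesh = tessellate(surf, 32, 8)
        assert mesh.area == pytest.approx(2 * np.pi * 3 * 10, rel=0.05)


class TestCoons:
    def test_flat_square_is_bilinear(self):
        patch = coons_patch([_seg([0, 0, 0], [1, 0, 0]),
                             _seg([1, 0, 0], [1, 1, 0]),
                             _seg([0, 1, 0], [1, 1, 0]),
                             _seg([0, 0, 0], [0, 1, 0])])
        assert np.allclose(patch.evaluate(0.5, 0.5), [0.5, 0.5, 0])

    def test_boundary_reproduction_with_lifted_edge(self):
        lifted = BSplineCurve(np.array([[0, 1, 0], [0.5, 1, 2.0], [1, 1, 0]]),
                              degree=2)
        patch = coons_patch([_seg([0, 0, 0], [1, 0, 0]),
                             _seg([1, 0, 0], [1, 1, 0]),
                             lifted,
                             _seg([0, 0, 0], [0, 1, 0])])
        u = np.linspace(0, 1, 33)
        top = patch.evaluate(u, np.ones_like(u))
        assert np.allclose(top, lifted.evaluate(u), atol=1e-12)
        # lifted edge midpoint reproduced exactly (arc height 1 at midpoint)
        assert np.allclose(patch.evaluate(0.5, 1.0), [0.5, 1.0, 1.0])

    def test_quarter_cylinder_regression(self):
        r, h = 3.0, 5.0
        ang = np.linspace(0, np.pi / 2, 9)
        arc0 = interpolating_open_curve(
            np.c_[r * np.cos(ang), r * np.sin(ang), np.zeros(9)])
        arc1 = interpolating_open_curve(
            np.c_[r * np.cos(ang), r * np.sin(ang), np.full(9, h)])
        patch = coons_patch([arc0, _seg([0, r, 0], [0, r, h]), arc1,
                             _seg([r, 0, 0], [r, 0, h])])
        u = np.linspace(0, 1, 101)
        pts = patch.evaluate(*np.meshgrid(u, u)).reshape(-1, 3)
        dev = np.abs(np.linalg.norm(pts[:, :2], axis=1) - r)
        # dense-sampling oracle regression number (limited by the arc fit)
        assert dev.max() < 5e-4

    def test_open_boundary_loop_rejected(self):
        with pytest.raises(GeometryError):
            coons_patch([_seg([0, 0, 0], [1, 0, 0]),
                         _seg([1, 0.5, 0], [1, 1, 0]),   # 0.5 mm gap
                         _seg([0, 1, 0], [1, 1, 0]),
                         _seg([0, 0, 0], [0, 1, 0])])


class TestRevolution:
    def test_vertical_segment_revolves_to_cylinder(self):
        profile = BSplineCurve(np.array([[2, 0, 0], [2, 0, 6]]), degree=1)
        mesh = tessellate(revolve_profile(profile), 64, 8)
        assert mesh.area == pytest.approx(2 * np.pi * 2 * 6, rel=0.02)

    def test_semicircle_revolves_to_sphere(self):
        t = np.linspace(0, np.pi, 17)
        profile = interpolating_open_curve(
            np.c_[5 * np.sin(t), np.zeros(17), -5 * np.cos(t)])
        mesh = tessellate(revolve_profile(profile), 128, 64)
        assert mesh.area == pytest.approx(4 * np.pi * 25, rel=0.02)
        assert is_closed(mesh)

    def test_taper_to_axis_gives_single_apex_fan(self):
        profile = BSplineCurve(np.array([[2, 0, 0], [0, 0, 5]]), degree=1)
        mesh = tessellate(revolve_profile(profile), 32, 8)
        apex = np.isclose(mesh.vertices[:, 2], 5.0, atol=1e-9)
        assert apex.sum() == 1
        apex_idx = int(np.nonzero(apex)[0][0])
        fan = (mesh.faces == apex_idx).any(axis=1).sum()
        assert fan == 32

    def test_profile_crossing_axis_rejected(self):
        profile = BSplineCurve(np.array([[-1, 0, 0], [2, 0, 5]]), degree=1)
        with pytest.raises(GeometryError):
            revolve_profile(profile)


class TestTessellation:
    def test_refinement_does_not_increase_sphere_deviation(self):
        from dentiform.spatial import MeshProximity

        t = np.linspace(0, np.pi, 17)
        profile = interpolating_open_curve(
            np.c_[5 * np.sin(t), np.zeros(17), -5 * np.cos(t)])
        surf = revolve_profile(profile)
        uu, vv = np.meshgrid(np.linspace(0, 1, 120, endpoint=False),
                             np.linspace(0.01, 0.99, 60))
        dense = surf.evaluate(uu, vv).reshape(-1, 3)

        def max_dev(nu, nv):
            _, d, _ = MeshProximity(tessellate(surf, nu, nv)).closest(dense)
            return d.max()

        coarse, fine = max_dev(32, 16), max_dev(64, 32)
        assert fine <= coarse + 1e-12
        assert fine <= 0.6 * coarse  # chordal error shrinks ~quadratically

    def test_sphere_tessellation_watertight_after_pole_welding(self):
        t = np.linspace(0, np.pi, 17)
        profile = interpolating_open_curve(
            np.c_[5 * np.sin(t), np.zeros(17), -5 * np.cos(t)])
        mesh = tessellate(revolve_profile(profile), 128, 64)
        assert is_closed(mesh)
        # every edge shared by exactly two faces
        assert np.all(np.bincount(mesh.edges_unique_inverse) == 2)

    def test_minimum_grid_rejected(self):
        surf = loft_sections([circle_section(3, 0), circle_section(3, 10)])
        with pytest.raises(GeometryError):
            tessellate(surf, 2, 8)
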