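"""Lofting, branch combination, inlet extension and flattening."""

import numpy as np
import pytest

from eecp_hemoflow.mesh import LABEL_EXTENSION, SurfaceMesh
from eecp_hemoflow.reconstruct import (
    combine_branches,
    extend_inlet,
    flatten_surface,
    loft_contours,
)
from eecp_hemoflow.segment import circle_contour


def cylinder(radius=3e-3, n_slices=11, spacing=3e-3, n_ring=128):
    return loft_contours(
        [circle_contour((0, 0), radius, n_ring) for _ in range(n_slices)], spacing
    )


def tilted_branch(sign, radius=2e-3, half_deg=25.0, offset=1.2e-3, z0=30.5e-3):
    m = loft_contours(
        [circle_contour((0, 0), radius, 96) for _ in range(8)], 3e-3
    )
    half = np.radians(half_deg)
    c, s = np.cos(half), np.sin(half)
    Rm = np.array([[c, 0, sign * s], [0, 1, 0], [-sign * s, 0, c]])
    m.vertices = m.vertices @ Rm.T + np.array([sign * offset, 0, z0])
    return m


class TestLoft:
    def test_cylinder_area_closed_form(self):
        tube = cylinder()
        exact = 2 * np.pi * 3e-3 * 30e-3
        assert tube.area() == pytest.approx(exact, rel=0.02)

    def test_frustum_area_closed_form(self):
        cons = [circle_contour((0, 0), 3e-3 - 1e-3 * k / 10, 128) for k in range(11)]
        tube = loft_contours(cons, 3e-3)
        slant = np.hypot(30e-3, 1e-3)
        assert tube.area() == pytest.approx(np.pi * (3e-3 + 2e-3) * slant, rel=0.02)

    def test_uniform_band_equal_triangles(self):
        cons = [circle_contour((0, 0), 3e-3, 64) for _ in range(3)]
        tube = loft_contours(cons, 2e-3, n_ring=64)
        areas = tube.as_trimesh().area_faces
        assert np.allclose(areas, areas[0], rtol=1e-9)

    def test_capped_watertight(self):
        cap = cylinder().capped()
        assert cap.euler_characteristic() == 2
        assert cap.is_watertight()
        assert cap.as_trimesh().volume > 0

    def test_too_few_contours_rejected(self):
        with pytest.raises(ValueError):
            loft_contours([circle_contour((0, 0), 1.0)] * 2, 1.0)


@pytest.fixture(scope="module")
def parts():
    return cylinder(), tilted_branch(+1), tilted_branch(-1)


class TestCombine:
    def test_recombined_y_watertight(self, parts):
        trunk, a, b = parts
        comb = combine_branches(trunk, a, b)
        cap = comb.capped()
        assert cap.euler_characteristic() == 2
        assert cap.is_watertight()
        assert cap.as_trimesh().volume > 0

    def test_argument_order_congruence(self, parts):
        trunk, a, b = parts
        v1 = combine_branches(trunk, a, b).vertices
        v2 = combine_branches(trunk, b, a).vertices
        s1 = set(map(tuple, np.round(v1, 12)))
        s2 = set(map(tuple, np.round(v2, 12)))
        assert s1 == s2

    def test_area_bookkeeping(self, parts):
        trunk, a, b = parts
        comb = combine_branches(trunk, a, b)
        total = trunk.area() + a.area() + b.area()
        assert comb.area() == pytest.approx(total, rel=0.03)

    def test_distant_branches_rejected(self, parts):
        trunk, a, b = parts
        far = b.copy()
        far.vertices = far.vertices + np.array([0.0, 0.0, 0.5])
        with pytest.raises(ValueError, match="adjacent"):
            combine_branches(trunk, a, far)


class TestExtendInlet:
    def test_extension_length_five_radii(self):
        ext = extend_inlet(cylinder(radius=3e-3))
        assert ext.meta["extension_length"] == pytest.approx(15e-3, abs=1e-9)

    def test_elliptical_inlet_uses_mean_vertex_radius(self):
        th = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        ellipse = np.column_stack([3e-3 * np.cos(th), 2e-3 * np.sin(th)])
        tube = loft_contours([ellipse] * 5, 2e-3)
        pts = tube.vertices[tube.rings[0]]
        rbar = np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean()
        ext = extend_inlet(tube)
        assert ext.meta["extension_length"] == pytest.approx(5 * rbar, rel=1e-12)

    def test_double_extension_replaces(self):
        tube = cylinder()
        e1 = extend_inlet(tube)
        e2 = extend_inlet(e1)
        assert len(e2.vertices) == len(e1.vertices)
        assert e2.meta["extension_length"] == pytest.approx(
            e1.meta["extension_length"]
        )

    def test_inlet_cross_section_preserved(self):
        ext = extend_inlet(cylinder(radius=3e-3))
        ring = ext.vertices[ext.rings[0]]
        r = np.linalg.norm(ring[:, :2], axis=1)
        assert np.allclose(r, 3e-3, rtol=1e-9)

    def test_extension_faces_labelled(self):
        ext = extend_inlet(cylinder())
        assert np.any(ext.face_labels == LABEL_EXTENSION)
        assert ext.capped().euler_characteristic() == 2


class TestFlatten:
    def test_cylinder_chart_is_rectangle(self):
        fm = flatten_surface(cylinder())
        assert fm.theta.min() >= 0 and fm.theta.max() < 2 * np.pi
        assert fm.u.max() == pytest.approx(30e-3, rel=1e-9)
        ring0 = np.sort(fm.theta[fm.ring_index == 0])
        spacing = np.diff(ring0)
        assert (spacing.max() - spacing.min()) / spacing.mean() < 0.01

    def test_rotation_shifts_theta(self):
        tube = cylinder()
        fm0 = flatten_surface(tube)
        phi = 0.7
        c, s = np.cos(phi), np.sin(phi)
        rot = tube.copy()
        rot.vertices = rot.vertices @ np.array(
            [[c, -s, 0], [s, c, 0], [0, 0, 1]]
        ).T
        fm1 = flatten_surface(rot)
        d = np.mod(fm1.theta - fm0.theta, 2 * np.pi)
        assert np.allclose(np.minimum(d, 2 * np.pi - d), phi, atol=1e-9)
        assert np.allclose(fm1.u, fm0.u)

    def test_plaque_appears_in_radius_channel(self):
        # radius dips by 15% around u = 15 mm
        cons = []
        for k in range(21):
            z = k * 1.5e-3
            r = 3e-3 * (1 - 0.15 * np.exp(-0.5 * ((z - 15e-3) / 2e-3) ** 2))
            cons.append(circle_contour((0, 0), r, 96))
        tube = loft_contours(cons, 1.5e-3)
        fm = flatten_surface(tube)
        u_min = fm.u[np.argmin(fm.radius)]
        assert abs(u_min - 15e-3) <= 2e-3
        assert fm.radius.min() == pytest.approx(0.85 * 3e-3, rel=0.01)

    def test_unstructured_mesh_rejected(self):
        tube = cylinder()
        bare = SurfaceMesh(tube.vertices, tube.faces)
        with pytest.raises(ValueError, match="split"):
            flatten_surface(bare)
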