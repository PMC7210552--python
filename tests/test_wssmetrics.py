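"""Hemodynamic index engine: closed forms, invariants, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eecp_hemoflow.flow import WallShearField
from eecp_hemoflow.mesh import SurfaceMesh
from eecp_hemoflow.wssmetrics import (
    awss,
    awssg,
    compute_metric_field,
    mesh_independence,
    osi,
    percent_change,
    rrt,
    summarize,
    wssg_instant,
)

from conftest import make_series

T = 0.8


def flat_grid_mesh(nx=12, ny=12, size=1.0):
    xs = np.linspace(0, size, nx)
    ys = np.linspace(0, size, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append((a, b, a + 1))
            faces.append((b, b + 1, a + 1))
    return SurfaceMesh(verts, np.array(faces))


class TestAwss:
    def test_constant_series(self):
        s = make_series(lambda t: [[2.0, 0.0, 0.0]])
        assert awss(s)[0] == pytest.approx(2.0)

    def test_rectified_sine_closed_form(self):
        s = make_series(lambda t: [[np.pi * np.sin(2 * np.pi * t / T), 0, 0]])
        assert awss(s)[0] == pytest.approx(2.0, abs=1e-4)

    def test_positive_homogeneity(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(5, 64, 3))
        t = np.linspace(0, T, 64, endpoint=False)
        s1 = WallShearField(np.zeros((5, 3)), base, t, T)
        s3 = WallShearField(np.zeros((5, 3)), 3.0 * base, t, T)
        assert np.allclose(awss(s3), 3.0 * awss(s1))

    def test_nonuniform_grid_rejected(self):
        t = np.sort(np.random.default_rng(0).uniform(0, T, 32))
        s = WallShearField(np.zeros((1, 3)), np.ones((1, 32, 3)), t, T)
        with pytest.raises(ValueError):
            awss(s)


class TestOsi:
    def test_unidirectional_is_zero(self):
        s = make_series(lambda t: [[1.0 + np.sin(2 * np.pi * t / T) ** 2, 0, 0]])
        val, flagged = osi(s)
        assert val[0] == pytest.approx(0.0, abs=1e-12)
        assert not flagged[0]

    def test_sign_reversing_is_half(self):
        s = make_series(lambda t: [[np.sin(2 * np.pi * t / T), 0, 0]])
        val, _ = osi(s)
        assert val[0] == pytest.approx(0.5, abs=1e-6)

    def test_piecewise_quarter(self):
        # +1 Pa for three quarters of the cycle, -1 Pa for one quarter:
        # |int tau| = T/2, int |tau| = T -> OSI = 1/2 (1 - 1/2) = 1/4
        n_t = 400
        tau = np.zeros((1, n_t, 3))
        tau[0, : 3 * n_t // 4, 0] = 1.0
        tau[0, 3 * n_t // 4 :, 0] = -1.0
        t = np.linspace(0, T, n_t, endpoint=False)
        s = WallShearField(np.zeros((1, 3)), tau, t, T)
        val, _ = osi(s)
        assert val[0] == pytest.approx(0.25, abs=1e-9)

    def test_zero_series_flagged(self):
        s = make_series(lambda t: [[0.0, 0.0, 0.0]])
        val, flagged = osi(s)
        assert val[0] == 0.0 and flagged[0]

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        n_t = rng.integers(8, 128)
        tau = rng.normal(scale=rng.uniform(0.1, 10.0), size=(3, n_t, 3))
        t = np.linspace(0, T, n_t, endpoint=False)
        s = WallShearField(np.zeros((3, 3)), tau, t, T)
        val, _ = osi(s)
        assert np.all((val >= 0.0) & (val <= 0.5))


class TestWssg:
    def test_uniform_field_zero(self):
        mesh = flat_grid_mesh()
        assert np.allclose(wssg_instant(np.full(len(mesh.vertices), 5.0), mesh), 0.0)

    def test_linear_field_exact(self):
        mesh = flat_grid_mesh()
        vals = 3.0 * mesh.vertices[:, 0]
        assert np.allclose(wssg_instant(vals, mesh), 3.0, atol=1e-9)

    def test_two_component_linear_field(self):
        mesh = flat_grid_mesh()
        vals = 3.0 * mesh.vertices[:, 0] + 4.0 * mesh.vertices[:, 1]
        assert np.allclose(wssg_instant(vals, mesh), 5.0, atol=1e-9)

    def test_polyline_gradient(self):
        pts = np.column_stack([np.linspace(0, 1, 21), np.zeros(21), np.zeros(21)])
        vals = 7.0 * pts[:, 0]
        assert np.allclose(wssg_instant(vals, pts), 7.0)

    def test_isolated_points_rejected(self):
        with pytest.raises(ValueError):
            wssg_instant(np.array([1.0, 2.0]), np.zeros((2, 3)))


class TestAwssg:
    @pytest.fixture()
    def mesh(self):
        return flat_grid_mesh()

    def test_time_constant_linear_field(self, mesh):
        x = mesh.vertices[:, 0]
        s = make_series(
            lambda t: np.column_stack([3.0 * x, np.zeros_like(x), np.zeros_like(x)]),
            points=mesh.vertices,
        )
        assert np.allclose(awssg(s, mesh), 3.0, atol=1e-9)

    def test_separable_rectified_sine(self, mesh):
        x = mesh.vertices[:, 0]
        s = make_series(
            lambda t: np.column_stack(
                [3.0 * x * abs(np.sin(2 * np.pi * t / T)), np.zeros_like(x),
                 np.zeros_like(x)]
            ),
            points=mesh.vertices,
        )
        assert np.allclose(awssg(s, mesh), 3.0 * 2 / np.pi, atol=1e-3)

    def test_rotation_invariance(self, mesh):
        rng = np.random.default_rng(3)
        x = mesh.vertices[:, 0]
        tau_fn = lambda t: np.column_stack(
            [2.0 * x + np.sin(2 * np.pi * t / T), np.zeros_like(x), np.zeros_like(x)]
        )
        s = make_series(tau_fn, points=mesh.vertices)
        base = awssg(s, mesh)
        # rotate geometry and shear vectors rigidly
        from scipy.spatial.transform import Rotation

        Rm = Rotation.random(random_state=7).as_matrix()
        mesh_rot = SurfaceMesh(mesh.vertices @ Rm.T, mesh.faces)
        s_rot = WallShearField(
            s.points @ Rm.T, s.tau @ Rm.T, s.t, s.period
        )
        assert np.allclose(awssg(s_rot, mesh_rot), base, atol=1e-9)


class TestRrt:
    def test_reference_values(self):
        assert rrt(0.0, 4.0) == pytest.approx(0.25)
        assert rrt(0.25, 2.0) == pytest.approx(1.0)

    def test_singular_is_flagged_infinite(self):
        out = rrt(0.5, 4.0)
        assert np.isinf(out) and not np.isnan(out)
        assert np.isinf(rrt(0.1, 0.0))

    def test_identity(self):
        rng = np.random.default_rng(5)
        o = rng.uniform(0.0, 0.49, 100)
        a = rng.uniform(0.1, 10.0, 100)
        assert np.allclose(rrt(o, a) * (1 - 2 * o) * a, 1.0)


class TestAgainstBruteForceOracle:
    """Indices agree with direct Riemann sums on 10x oversampled series."""

    @pytest.mark.parametrize("seed", range(50))
    def test_random_fixture(self, seed):
        rng = np.random.default_rng(seed)
        n_t = 128
        # band-limited random periodic series per point
        t = np.linspace(0, T, n_t, endpoint=False)
        t10 = np.linspace(0, T, n_t * 10, endpoint=False)

        def series_at(tgrid):
            out = np.zeros((2, len(tgrid), 3))
            for p in range(2):
                for c in range(3):
                    for k in range(1, 4):
                        amp = coef[p, c, k - 1]
                        pha = phas[p, c, k - 1]
                        out[p, :, c] += amp * np.cos(2 * np.pi * k * tgrid / T + pha)
            return out

        coef = rng.normal(size=(2, 3, 3))
        phas = rng.uniform(0, 2 * np.pi, size=(2, 3, 3))
        s = WallShearField(np.zeros((2, 3)), series_at(t), t, T)
        fine = series_at(t10)
        # oracle: plain Riemann sums on the oversampled series
        awss_oracle = np.linalg.norm(fine, axis=2).mean(axis=1)
        mean_vec = fine.mean(axis=1)
        osi_oracle = 0.5 * (
            1 - np.linalg.norm(mean_vec, axis=1) / np.linalg.norm(fine, axis=2).mean(axis=1)
        )
        assert np.allclose(awss(s), awss_oracle, rtol=2e-3)
        assert np.allclose(osi(s)[0], osi_oracle, atol=2e-3)


class TestInvariances:
    def test_time_shift_invariance(self):
        rng = np.random.default_rng(11)
        n_t = 200
        t = np.linspace(0, T, n_t, endpoint=False)
        tau = rng.normal(size=(4, n_t, 3))
        s = WallShearField(np.zeros((4, 3)), tau, t, T)
        shifted = WallShearField(np.zeros((4, 3)), np.roll(tau, 37, axis=1), t, T)
        assert np.allclose(awss(s), awss(shifted))
        assert np.allclose(osi(s)[0], osi(shifted)[0])

    def test_point_permutation_invariance(self):
        mesh = flat_grid_mesh(6, 6)
        x = mesh.vertices[:, 0]
        s = make_series(
            lambda t: np.column_stack(
                [x + np.cos(2 * np.pi * t / T), x * 0, x * 0]
            ),
            points=mesh.vertices,
        )
        field = compute_metric_field(s, geometry=mesh)
        perm = np.random.default_rng(2).permutation(len(mesh.vertices))
        inv = np.argsort(perm)
        mesh_p = SurfaceMesh(mesh.vertices[perm], inv[mesh.faces])
        s_p = WallShearField(s.points[perm], s.tau[perm], s.t, s.period)
        field_p = compute_metric_field(s_p, geometry=mesh_p)
        assert np.allclose(field_p.awss, field.awss[perm])
        assert np.allclose(field_p.awssg, field.awssg[perm])


class TestSummariesAndChanges:
    def test_summarize_constant_field(self):
        from eecp_hemoflow.wssmetrics import MetricField

        f = MetricField(
            awss=np.full(5, 2.0), osi=np.full(5, 0.1), rrt=np.full(5, 0.625)
        )
        table = summarize(f)
        assert table.loc["Max", "AWSS (Pa)"] == table.loc["Min", "AWSS (Pa)"] == 2.0

    def test_summarize_ordering_invariant(self):
        from eecp_hemoflow.wssmetrics import MetricField

        f = MetricField(
            awss=np.array([1.0, 2.0, 3.0]),
            osi=np.zeros(3),
            rrt=np.array([1.0, 0.5, 1 / 3]),
        )
        table = summarize(f)
        assert (
            table.loc["Max", "AWSS (Pa)"],
            table.loc["Min", "AWSS (Pa)"],
            table.loc["Mean", "AWSS (Pa)"],
        ) == (3.0, 1.0, 2.0)

    @pytest.mark.parametrize(
        "pre,during,expected",
        [
            (6.76, 7.90, 16.9),
            (1.68e3, 2.01e3, 19.6),
            (2.12e4, 2.60e4, 22.6),
            (5.0, 5.0, 0.0),
        ],
    )
    def test_percent_change(self, pre, during, expected):
        assert percent_change(pre, during) == expected

    def test_percent_change_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestMeshIndependence:
    def test_reference_pre_values(self):
        table, verdict = mesh_independence(
            [(259706, 7.772), (419466, 7.921), (720085, 7.966), (907589, 7.991)]
        )
        assert table.successive_change.iloc[-1] == pytest.approx(0.0031, abs=2e-4)
        assert verdict

    def test_reference_during_values(self):
        table, verdict = mesh_independence(
            [(259706, 9.043), (419466, 9.236), (720085, 9.359), (907589, 9.372)]
        )
        assert table.successive_change.iloc[-1] == pytest.approx(0.0014, abs=2e-4)
        assert verdict

    def test_identical_values_zero_changes(self):
        table, verdict = mesh_independence([(10, 1.0), (20, 1.0), (30, 1.0)])
        assert np.allclose(table.successive_change.iloc[1:], 0.0)
        assert verdict

    def test_duplicate_sizes_rejected(self):
        with pytest.raises(ValueError):
            mesh_independence([(10, 1.0), (10, 1.1)])
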