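"""Flow solvers against closed-form oracles and conservation properties."""

import numpy as np
import pytest

from eecp_hemoflow.flow import (
    FluidProps,
    SolverConfig,
    analytic_womersley,
    poiseuille_wss,
    report_diastolic_snapshot,
    solve_channel_2d,
    solve_pulsatile_flow,
    solve_pulsatile_tube,
    womersley_number,
)

PROPS = FluidProps()
R = 3e-3
T = 0.8
OMEGA = 2 * np.pi / T


def steady(u0):
    return lambda t: u0 * np.ones_like(np.asarray(t, dtype=float))


class TestAnalyticWomersley:
    def test_alpha_for_reference_conditions(self):
        # R = 3 mm, T = 0.8 s, rho = 1050, mu = 3.5e-3 -> alpha near 4.6
        assert womersley_number(R, PROPS, OMEGA) == pytest.approx(4.6, abs=0.05)

    def test_low_frequency_limit_is_poiseuille(self):
        omega = (0.05 / R) ** 2 * PROPS.mu / PROPS.rho  # alpha = 0.05
        sol = analytic_womersley(R, PROPS, omega, mean_velocity_amplitude=0.1)
        r = np.linspace(0, R, 50)
        parabola = 2 * 0.1 * (1 - (r / R) ** 2)
        assert np.max(np.abs(sol.velocity(r, 0.0) - parabola)) / parabola.max() < 1e-3

    def test_phase_lead_tends_to_45_degrees(self):
        leads = []
        for alpha in (5.0, 20.0, 100.0):
            omega = (alpha / R) ** 2 * PROPS.mu / PROPS.rho
            sol = analytic_womersley(R, PROPS, omega, mean_velocity_amplitude=0.1)
            leads.append(np.degrees(sol.wss_phase_lead()))
        assert all(b > a for a, b in zip(leads, leads[1:]))
        assert leads[-1] == pytest.approx(45.0, abs=1.0)

    def test_steady_branch_on_nonpositive_omega(self):
        sol = analytic_womersley(R, PROPS, 0.0, mean_velocity_amplitude=0.3)
        assert sol.wss(0.0) == pytest.approx(poiseuille_wss(0.3, R, PROPS.mu))


class TestTubeSolver:
    def test_steady_matches_poiseuille(self):
        res = solve_pulsatile_tube(R, steady(0.3), PROPS, SolverConfig(), period=T)
        exact = poiseuille_wss(0.3, R, PROPS.mu)  # = 8 mu U / D = 1.4 Pa
        assert exact == pytest.approx(1.4, abs=1e-12)
        assert np.mean(res.wss) == pytest.approx(exact, rel=0.02)

    def test_oscillatory_matches_womersley(self):
        sol = analytic_womersley(R, PROPS, OMEGA, mean_velocity_amplitude=0.2)
        res = solve_pulsatile_tube(
            R, lambda t: 0.2 * np.cos(OMEGA * np.asarray(t)), PROPS,
            SolverConfig(), period=T,
        )
        tau = sol.wss(res.t)
        rms = np.sqrt(np.mean((res.wss - tau) ** 2) / np.mean(tau**2))
        assert rms < 0.03

    def test_zero_inlet_rest_state(self):
        res = solve_pulsatile_tube(R, steady(0.0), PROPS, SolverConfig(), period=T)
        assert np.allclose(res.u, 0.0, atol=1e-14)
        assert np.allclose(res.wss, 0.0, atol=1e-12)
        assert np.allclose(res.pressure_gradient, 0.0, atol=1e-9)

    def test_grid_refinement_convergence(self):
        vals = []
        for n_r in (48, 64):
            cfg = SolverConfig(n_radial=n_r)
            res = solve_pulsatile_tube(R, steady(0.3), PROPS, cfg, period=T)
            vals.append(np.mean(res.wss))
        assert abs(vals[1] - vals[0]) / vals[0] < 0.01

    def test_cycle_periodicity(self, wave_spec):
        from eecp_hemoflow.synthdata import generate_velocity_waveform

        w = generate_velocity_waveform(wave_spec, "during")
        res = solve_pulsatile_tube(R, w, PROPS, SolverConfig())
        assert res.cycle_periodicity_rms < 0.01

    def test_residuals_below_tolerance(self):
        res = solve_pulsatile_tube(R, steady(0.3), PROPS, SolverConfig(), period=T)
        assert res.residual_history.max() < 1e-5

    def test_wall_shear_field_is_tangential(self):
        res = solve_pulsatile_tube(R, steady(0.3), PROPS, SolverConfig(), period=T)
        wall = res.wall_shear_field(n_axial=4, length=0.02)
        # wall normal of a z-aligned tube is radial; tau is axial
        mags = wall.magnitudes()
        assert np.allclose(wall.tau[:, :, :2], 0.0)
        assert mags.shape == (4, len(res.t))


class TestChannelSolver:
    def test_steady_plane_poiseuille(self):
        H, L, U = 2e-3, 16e-3, 0.02
        cfg = SolverConfig(nx=96, ny=24)
        res = solve_channel_2d(L, H, U, PROPS, cfg, steady=True)
        exact = 6 * PROPS.mu * U / H
        m = (res.x > 0.6 * L) & (res.x < 0.9 * L)
        assert np.mean(res.wss_bottom[0][m]) == pytest.approx(exact, rel=0.02)
        assert res.mass_residual < 1e-10

    def test_oscillatory_linearity_at_low_reynolds(self):
        H, L = 2e-3, 8e-3
        cfg = SolverConfig(nx=48, ny=16, n_cycles=2, timesteps_per_cycle=50)
        amps = []
        for u0 in (0.002, 0.004):
            res = solve_channel_2d(
                L, H, lambda t: u0 * (1 + 0.5 * np.sin(OMEGA * t)), PROPS, cfg,
                period=T,
            )
            m = res.x > 0.5 * L
            amps.append(np.ptp(res.wss_bottom[:, m].mean(axis=1)))
        assert amps[1] / amps[0] == pytest.approx(2.0, rel=0.05)


class TestDispatchAndSnapshots:
    def test_dispatch_tube(self):
        field, wall = solve_pulsatile_flow(
            {"kind": "tube", "radius": R, "length": 0.02, "n_axial": 3, "period": T},
            steady(0.2),
            PROPS,
            SolverConfig(),
        )
        assert field.kind == "tube"
        assert wall.n_points == 3

    def test_unknown_domain_rejected(self):
        with pytest.raises(ValueError):
            solve_pulsatile_flow({"kind": "sphere"}, steady(0.1), PROPS)

    def test_snapshot_zero_frac_is_first_step(self):
        res = solve_pulsatile_tube(R, steady(0.3), PROPS, SolverConfig(), period=T)
        snap = report_diastolic_snapshot(res.to_field(length=0.02), 0.0)
        assert snap["index"] == 0

    def test_snapshot_constant_solution_independent_of_frac(self):
        res = solve_pulsatile_tube(R, steady(0.3), PROPS, SolverConfig(), period=T)
        f = res.to_field(length=0.02)
        a = report_diastolic_snapshot(f, 0.1)
        b = report_diastolic_snapshot(f, 0.7)
        assert np.allclose(a["velocity"], b["velocity"], rtol=1e-6)

    def test_augmented_diastole_raises_velocity(self, wave_spec):
        from dataclasses import replace

        from eecp_hemoflow.synthdata import generate_velocity_waveform

        pre = generate_velocity_waveform(wave_spec, "pre")
        during = generate_velocity_waveform(wave_spec, "during")
        cfg = SolverConfig()
        rp = solve_pulsatile_tube(R, pre, PROPS, cfg)
        rd = solve_pulsatile_tube(R, during, PROPS, cfg)
        for frac in (0.54, 0.58):
            sp = report_diastolic_snapshot(rp.to_field(), frac)
            sd = report_diastolic_snapshot(rd.to_field(), frac)
            assert sd["mean_velocity"] > sp["mean_velocity"]
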