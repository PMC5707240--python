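"""Time integration, work accounting, periodicity and the uniform-stress
comparison."""

import numpy as np
import pandas as pd
import pytest

from lvdyn import (CirculationParams, ModelConfig, Simulator, SolverSettings,
                   arts_ratio)
from lvdyn.simulator import MJ_PER_KPA_CM3

from conftest import CONVERGED, converged_mean


class TestArtsRatio:
    def test_thin_wall_limit(self):
        assert arts_ratio(1e-9, 60.0) == pytest.approx(0.0, abs=1e-9)

    def test_tabulated_volume_ratio(self):
        expected = np.log(1 + 158.112 / 59.8714) / 3
        assert arts_ratio(158.112, 59.8714) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_strictly_increasing_in_volume_ratio(self):
        r = arts_ratio(np.linspace(10, 300, 50), 60.0)
        assert np.all(np.diff(r) > 0)

    def test_invalid_volumes_rejected(self):
        with pytest.raises(ValueError):
            arts_ratio(-1.0, 60.0)


class TestFixedPoint:
    def test_unloaded_reference_state_is_stationary(self):
        """With every source pressure at zero and the wall at its unloaded
        reference shape, a step changes nothing."""
        cfg = ModelConfig(
            circulation=CirculationParams(P_PA=0.0, P_SV=1e-12),
            P_A0=0.0, P_AO0=0.0,
            solver=SolverSettings(dt_base=1e-3, dt_min=1e-3, n_cycles=1))
        sim = Simulator(cfg)
        # t in diastole: activation off
        ydot, diag = sim._stage(0.5, np.zeros(5))
        np.testing.assert_allclose(ydot, 0.0, atol=1e-9)
        assert diag["p"] == pytest.approx(0.0, abs=1e-9)


class TestConvergenceOrder:
    def test_rk2_observed_order_at_least_1_8(self):
        """Step-halving study over a smooth early-systolic window."""
        t_end = 0.06
        sols = []
        for dt in (2e-4, 1e-4, 5e-5):
            cfg = ModelConfig(solver=SolverSettings(dt_base=dt, dt_min=dt,
                                                    n_cycles=1))
            sim = Simulator(cfg)
            y = np.array([0.0, 0.0, 0.0, cfg.P_A0, cfg.P_AO0])
            t = 0.0
            while t < t_end - 1e-12:
                h = min(dt, t_end - t)
                k1, _ = sim._stage(t, y)
                k2, _ = sim._stage(t + h, y + h * k1)
                y = y + 0.5 * h * (k1 + k2)
                t += h
            sols.append(y.copy())
        e1 = np.linalg.norm(sols[0] - sols[2])
        e2 = np.linalg.norm(sols[1] - sols[2])
        # with E(dt) = C dt^p on grids (dt, dt/2, dt/4): e1/e2 = 2^p + 1
        order = np.log2(e1 / e2 - 1.0)
        assert order >= 1.8


class TestWorkLedger:
    def test_internal_work_decomposition(self, normal_run):
        w = normal_run.work
        np.testing.assert_allclose(
            w["internal_work"],
            w["fiber_work"] + w["viscous_work"] + w["elastic_net"],
            rtol=1e-12)

    def test_viscous_dissipation_nonpositive(self, normal_run):
        assert (normal_run.work["viscous_work"] <= 0).all()

    def test_elastic_energy_closed_over_converged_cycles(self, normal_run):
        """The elastic stress is conservative: its net work over a periodic
        cycle is below 0.2% of stroke work."""
        w = normal_run.work[normal_run.work["cycle"].isin(CONVERGED)]
        ratio = (w["elastic_net"].abs() / w["stroke_work"]).max()
        assert ratio < 0.002

    def test_internal_equals_external_work(self, normal_run):
        """Power balance of the weak form: the internal stress power equals
        the boundary work at every instant, so the cycle integrals agree."""
        w = normal_run.work[normal_run.work["cycle"].isin(CONVERGED)]
        np.testing.assert_allclose(w["internal_work"], w["external_work"],
                                   rtol=1e-6)

    def test_stroke_work_positive_and_physiological(self, normal_run):
        w = converged_mean(normal_run.work, "stroke_work")
        assert 0.3 < w < 3.0   # J; sanity band for a human-sized LV


class TestPeriodicity:
    def test_stroke_work_drift_below_tenth_percent(self, normal_run):
        w = normal_run.work["stroke_work"].to_numpy()
        assert abs(w[-1] - w[-2]) / w[-1] < 1e-3

    def test_volume_loop_closes(self, normal_run):
        ts = normal_run.timeseries
        T_c = normal_run.config.active.T_c
        n = normal_run.config.solver.n_cycles
        V_end = ts["V"].iloc[-1]
        V_prev = float(np.interp((n - 1) * T_c, ts["t"], ts["V"]))
        assert abs(V_end - V_prev) / V_end < 1e-3

    def test_flow_conservation_in_periodic_state(self, normal_run):
        """Mitral inflow equals aortic outflow (the stroke volume) over a
        converged cycle to 0.5%."""
        sv_in, sv_out = [], []
        for c in CONVERGED:
            df = normal_run.cycle_slice(c)
            sv_in.append(np.trapezoid(df["q_mv"], df["t"]))
            sv_out.append(np.trapezoid(df["q_ao"], df["t"]))
        sv_in, sv_out = np.mean(sv_in), np.mean(sv_out)
        assert sv_in == pytest.approx(sv_out, rel=5e-3)
        assert 30.0 < sv_out < 120.0   # cm^3, physiological stroke volume

    def test_physiological_pressure_ordering(self, normal_run):
        ts = normal_run.cycle_slice(10)
        # peak systolic LV pressure reaches the aortic pressure range
        assert ts["p"].max() > ts["P_AO"].median()
        # valves never both wide open
        both_open = ((ts["R_MV"] < 2 * normal_run.config.circulation.R_op_mv)
                     & (ts["R_AOV"] < 2
                        * normal_run.config.circulation.R_op_aov))
        assert not both_open.any()


class TestDiagnostics:
    def test_stage_constraint_residual_tiny(self):
        cfg = ModelConfig(solver=SolverSettings(n_cycles=1))
        sim = Simulator(cfg)
        y = np.array([0.01, -0.02, 0.005, 1.4, 11.0])
        _, diag = sim._stage(0.13, y)
        assert abs(diag["constraint_residual"]) < 1e-7

    def test_deterministic_restart(self):
        cfg = ModelConfig(solver=SolverSettings(n_cycles=1))
        r1 = Simulator(cfg).run(1).timeseries
        r2 = Simulator(cfg).run(1).timeseries
        pd.testing.assert_frame_equal(r1, r2)

    def test_field_snapshot_contents(self, normal_run):
        assert set(normal_run.fields) == {"end_diastole", "peak_activation",
                                          "end_systole"}
        f = normal_run.fields["peak_activation"]
        tr = f["sigma_mumu"] + f["sigma_nunu"] + f["sigma_phiphi"]
        np.testing.assert_allclose(tr, 0.0, atol=1e-8)
        assert (f["lambda_f"] > 0).all()

    def test_peak_fiber_stress_pattern(self, normal_run):
        """Qualitative expectation (not a hard failure): peak-systole fiber
        stress is largest near the midwall at the equatorial end."""
        import warnings

        f = normal_run.fields["peak_activation"]
        grid = normal_run.grid
        eq_band = f[np.isclose(f["nu0"], grid.nu0.min())
                    | (f["nu0"] < np.pi / 2 + 0.6)]
        idx = eq_band["sigma_ff"].idxmax()
        mu_star = f.loc[idx, "mu0"]
        mid = 0.5 * (grid.mu0.min() + grid.mu0.max())
        span = grid.mu0.max() - grid.mu0.min()
        if abs(mu_star - mid) > 0.45 * span:
            warnings.warn("peak sigma_ff not near the midwall "
                          f"(mu0 = {mu_star:.3f})")
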