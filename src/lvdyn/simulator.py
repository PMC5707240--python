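"""Time integration of the coupled LV-circulation system.

State vector y = (a1, a2, a3, P_A, P_AO).  At every Runge-Kutta stage the
three weak-form balance equations M adot = b p - g (linear in the rates) are
combined with the cavity flow constraint

    dV/dt - (P_A - p)/R_MV + (p - P_aov)/R_AOV = 0

and the implicit proximal aortic node, and solved for the algebraic unknowns
(p, P_aov) by a damped 2-variable Newton iteration; the rates then follow by
a 3x3 linear solve.  Explicit second-order Runge-Kutta (Heun) advances the
differential variables.  The system is stiff while a valve resistance is
switching, so the step is refined whenever a transvalvular pressure
difference lies inside the sigmoid transition band.

Work bookkeeping integrates the instantaneous powers recorded at every
accepted state (trapezoidal in time): fiber work -int S_f : Edot dV0 dt,
viscous work -int S_v : Edot (always <= 0), net elastic work (~0 over a
closed cycle), external boundary work, and stroke work -int p dV.
1 kPa cm^3 = 1 mJ, reported in J.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circulation import (CirculationParams, CirculationState, _sigmoid,
                          circuit_rates, solve_proximal_node, valve_resistances)
from .config import ModelConfig, SolverSettings
from .constitutive import activation
from .equilibrium import GeneralizedSystem, QuadratureGrid, assemble_balance
from .geometry import (DomainExitError, KinematicState, build_matched_shape,
                       deformation_tensors)

__all__ = ["Simulator", "SimulationResult", "run_cycles", "static_inflate",
           "arts_ratio", "shapes_experiment", "sensitivity_sweep"]

MJ_PER_KPA_CM3 = 1e-3  # 1 kPa cm^3 = 1 mJ


def arts_ratio(V_wall, V):
    """Uniform-fiber-stress prediction of the pressure-to-fiber-stress ratio,
    p / sigma_ff = (1/3) ln(1 + V_wall / V)."""
    if np.any(np.asarray(V) <= 0) or np.any(np.asarray(V_wall) <= 0):
        raise ValueError("volumes must be positive")
    return np.log1p(np.asarray(V_wall) / np.asarray(V)) / 3.0


@dataclass
class SimulationResult:
    timeseries: pd.DataFrame
    work: pd.DataFrame              # one row per cycle (J)
    fields: dict                    # phase name -> DataFrame on the grid
    config: ModelConfig
    grid: QuadratureGrid

    def cycle_slice(self, cycle: int) -> pd.DataFrame:
        T_c = self.config.active.T_c
        t = self.timeseries["t"].to_numpy()
        m = (t >= cycle * T_c - 1e-12) & (t <= (cycle + 1) * T_c + 1e-12)
        return self.timeseries[m]

    def stroke_volume(self, cycle: int) -> float:
        df = self.cycle_slice(cycle)
        return float(np.trapezoid(df["q_ao"], df["t"]))


class Simulator:
    """Coupled LV / circulation integrator for one configuration."""

    def __init__(self, config: ModelConfig | None = None):
        self.cfg = config or ModelConfig()
        s = self.cfg.solver
        self.grid = QuadratureGrid(self.cfg.geometry, self.cfg.fibers,
                                   n_mu=s.n_mu, n_nu=s.n_nu)
        self.eps_ed = np.zeros(self.grid.n_nodes)
        self._warm = None  # (p, P_aov) warm start

    # -- algebraic stage solve -------------------------------------------

    def _solve_pressures(self, sys: GeneralizedSystem, P_A, P_AO):
        """Solve the flow constraint + proximal node for (p, P_aov)."""
        cp = self.cfg.circulation
        Minv_b = np.linalg.solve(sys.M, sys.b)
        Minv_g = np.linalg.solve(sys.M, sys.g)
        alpha = float(sys.b @ Minv_b)
        gamma = float(sys.b @ Minv_g)
        bta, Rcc = cp.beta, cp.R_cc

        def residuals(p, pav):
            sm = _sigmoid(bta * (P_A - p))
            sa = _sigmoid(bta * (p - pav))
            Rmv = Rcc - (Rcc - cp.R_op_mv) * sm
            Rav = Rcc - (Rcc - cp.R_op_aov) * sa
            r1 = alpha * p - gamma - (P_A - p) / Rmv + (p - pav) / Rav
            r2 = (pav - P_AO) * Rav + (pav - p) * cp.R_AO
            return r1, r2, sm, sa, Rmv, Rav

        if self._warm is not None:
            p, pav = self._warm
        else:
            p, pav = P_A, P_AO
        scale = max(1.0, abs(P_A), abs(P_AO))
        tol = self.cfg.solver.newton_tol
        ok = False
        for _ in range(80):
            r1, r2, sm, sa, Rmv, Rav = residuals(p, pav)
            dRmv_dp = (Rcc - cp.R_op_mv) * sm * (1 - sm) * bta
            dRav = (Rcc - cp.R_op_aov) * sa * (1 - sa) * bta
            dRav_dp, dRav_dpav = -dRav, dRav
            J11 = (alpha + 1.0 / Rmv + (P_A - p) * dRmv_dp / Rmv**2
                   + 1.0 / Rav - (p - pav) * dRav_dp / Rav**2)
            J12 = -1.0 / Rav - (p - pav) * dRav_dpav / Rav**2
            J21 = (pav - P_AO) * dRav_dp - cp.R_AO
            J22 = Rav + (pav - P_AO) * dRav_dpav + cp.R_AO
            det = J11 * J22 - J12 * J21
            if det == 0 or not np.isfinite(det):
                break
            dp = (r1 * J22 - r2 * J12) / det
            dpav = (J11 * r2 - J21 * r1) / det
            # damp huge steps through the stiff sigmoid region
            lim = 5.0
            fac = min(1.0, lim / max(abs(dp), abs(dpav), lim))
            p -= fac * dp
            pav -= fac * dpav
            if max(abs(dp), abs(dpav)) < tol * scale:
                ok = True
                break
        if not ok:
            p = self._bisect_pressure(alpha, gamma, P_A, P_AO)
            pav = solve_proximal_node(p, P_AO, cp)
        else:
            # polish the inner node to its own tolerance
            pav = solve_proximal_node(p, P_AO, cp)
        Rmv, Rav = valve_resistances(P_A, p, pav, cp)
        self._warm = (p, pav)
        return p, pav, Rmv, Rav

    def _bisect_pressure(self, alpha, gamma, P_A, P_AO):
        """Robust fallback: the flow constraint is monotone increasing in p."""
        cp = self.cfg.circulation

        def f(p):
            pav = solve_proximal_node(p, P_AO, cp)
            Rmv, Rav = valve_resistances(P_A, p, pav, cp)
            return alpha * p - gamma - (P_A - p) / Rmv + (p - pav) / Rav

        lo, hi = -20.0, 80.0
        for _ in range(20):
            if f(lo) < 0:
                break
            lo *= 2
        for _ in range(20):
            if f(hi) > 0:
                break
            hi *= 2
        from scipy.optimize import brentq
        return brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)

    # -- stage evaluation -------------------------------------------------

    def _stage(self, t, y):
        """Rates and diagnostics at (t, y)."""
        cp = self.cfg.circulation
        a = KinematicState(*y[:3])
        P_A, P_AO = y[3], y[4]
        t_cyc = t % self.cfg.active.T_c
        if self.cfg.active.T_c - t_cyc < 1e-12:
            t_cyc = 0.0
        A = activation(t_cyc, self.eps_ed, self.cfg.active)
        sys = assemble_balance(self.grid, a, A, self.eps_ed, self.cfg.active,
                               self.cfg.passive, n_line=self.cfg.solver.n_line)
        p, pav, Rmv, Rav = self._solve_pressures(sys, P_A, P_AO)
        adot = np.linalg.solve(sys.M, sys.b * p - sys.g)
        circ = CirculationState(P_A=P_A, P_AO=P_AO, p=p, P_aov=pav,
                                R_MV=Rmv, R_AOV=Rav)
        dVdt = float(sys.b @ adot)
        dP_A, dP_AO, resid = circuit_rates(circ, dVdt, cp)
        ydot = np.array([adot[0], adot[1], adot[2], dP_A, dP_AO])
        diag = {
            "sys": sys, "p": p, "P_aov": pav, "R_MV": Rmv, "R_AOV": Rav,
            "adot": adot, "V": sys.V, "dVdt": dVdt,
            "q_mv": (P_A - p) / Rmv, "q_ao": (p - pav) / Rav,
            "P_fiber": sys.fiber_power(adot),
            "P_visc": sys.viscous_power(adot),
            "P_elastic": sys.elastic_power(adot),
            "P_ext": p * dVdt,
            "P_stroke": p * float(sys.dVda @ adot),
            "constraint_residual": resid,
        }
        return ydot, diag

    def _midwall_strain(self, a: KinematicState):
        if not hasattr(self, "_mid_ws"):
            from .geometry import MappingWorkspace
            g = self.cfg.geometry
            mu0 = 0.5 * (g.mu_in0 + g.mu_out0)
            self._mid_ws = MappingWorkspace(g, np.array([mu0]),
                                            np.array([3 * np.pi / 4]))
        E = self._mid_ws.tensors(a.a1, a.a2, a.a3)["E"][0]
        return E[2, 2], E[1, 1], E[1, 2]

    # -- time stepping ----------------------------------------------------

    def run(self, n_cycles: int | None = None,
            field_phases: dict | None = None) -> SimulationResult:
        """Integrate ``n_cycles`` cardiac cycles from the reference state."""
        cfg = self.cfg
        s = cfg.solver
        T_c = cfg.active.T_c
        n_cycles = n_cycles if n_cycles is not None else s.n_cycles
        t_end = n_cycles * T_c
        band = s.transition_band / cfg.circulation.beta
        if field_phases is None:
            field_phases = {"end_diastole": 0.0,
                            "peak_activation": cfg.active.T_a / 2,
                            "end_systole": cfg.active.T_a}

        y = np.array([0.0, 0.0, 0.0, cfg.P_A0, cfg.P_AO0])
        t = 0.0
        rows = []
        fields = {}
        phase_pending = {}

        while True:
            on_boundary = abs(t / T_c - round(t / T_c)) < 1e-9
            k1, d1 = self._stage(t, y)
            if on_boundary:
                lam = d1["sys"].lam_f
                self.eps_ed = 0.5 * (lam**2 - 1.0)
                cyc = int(round(t / T_c))
                if cyc == n_cycles - 1:
                    phase_pending = dict(field_phases)
            Ephi, Enu, Enuphi = self._midwall_strain(KinematicState(*y[:3]))
            rows.append((t, *y, *d1["adot"], d1["p"], d1["P_aov"],
                         d1["R_MV"], d1["R_AOV"], d1["V"], d1["dVdt"],
                         d1["q_mv"], d1["q_ao"], d1["P_fiber"], d1["P_visc"],
                         d1["P_elastic"], d1["P_ext"], d1["P_stroke"],
                         Ephi, Enu, Enuphi, float(np.max(d1["sys"].A))))

            # field snapshots in the final cycle
            t_cyc = t % T_c
            for name in list(phase_pending):
                if t_cyc >= phase_pending[name] - 1e-12:
                    fields[name] = self._field_snapshot(d1)
                    del phase_pending[name]

            if t >= t_end - 1e-12:
                break

            in_band = (abs(y[3] - d1["p"]) < band
                       or abs(d1["p"] - d1["P_aov"]) < band)
            dt = s.dt_min if in_band else s.dt_base
            next_boundary = (np.floor(t / T_c + 1e-9) + 1.0) * T_c
            dt = min(dt, next_boundary - t, t_end - t)

            while True:
                try:
                    y_pred = y + dt * k1
                    k2, _ = self._stage(t + dt, y_pred)
                    break
                except (DomainExitError, FloatingPointError):
                    if dt <= s.dt_min * (1 + 1e-9):
                        raise
                    dt = max(dt / 2.0, s.dt_min)
            y = y + 0.5 * dt * (k1 + k2)
            t = t + dt

        cols = ["t", "a1", "a2", "a3", "P_A", "P_AO", "da1", "da2", "da3",
                "p", "P_aov", "R_MV", "R_AOV", "V", "dVdt", "q_mv", "q_ao",
                "P_fiber", "P_visc", "P_elastic", "P_ext", "P_stroke",
                "E_phiphi", "E_nunu", "E_nuphi", "A_max"]
        ts = pd.DataFrame(rows, columns=cols)
        work = self._work_ledger(ts, n_cycles)
        return SimulationResult(timeseries=ts, work=work, fields=fields,
                                config=cfg, grid=self.grid)

    # -- work accounting --------------------------------------------------

    @staticmethod
    def _work_ledger(ts: pd.DataFrame, n_cycles: int,
                     T_c: float | None = None) -> pd.DataFrame:
        """Per-cycle work integrals (J) from the recorded powers.

        Sign convention: work done BY the tissue is positive, so each entry
        is minus the time integral of the corresponding S : Edot power.
        """
        if T_c is None:
            T_c = ts["t"].iloc[-1] / n_cycles
        t = ts["t"].to_numpy()
        out = []
        for c in range(n_cycles):
            m = (t >= c * T_c - 1e-12) & (t <= (c + 1) * T_c + 1e-12)
            seg = ts[m]
            tt = seg["t"].to_numpy()

            def W(col):
                return -MJ_PER_KPA_CM3 * float(np.trapezoid(seg[col], tt))

            fiber, visc, elast = W("P_fiber"), W("P_visc"), W("P_elastic")
            ext, stroke = W("P_ext"), W("P_stroke")
            out.append((c, fiber, visc, elast, fiber + visc + elast, ext,
                        stroke))
        return pd.DataFrame(out, columns=["cycle", "fiber_work",
                                          "viscous_work", "elastic_net",
                                          "internal_work", "external_work",
                                          "stroke_work"])

    # -- field snapshots ---------------------------------------------------

    def _field_snapshot(self, diag) -> pd.DataFrame:
        """Deviatoric Cauchy stress components and strains on the grid."""
        sys: GeneralizedSystem = diag["sys"]
        kin = sys.kin
        F, C, E = kin["F"], kin["C"], kin["E"]
        adot = diag["adot"]
        grid = self.grid
        # total PK2 without the reaction term (it is hydrostatic in the
        # Cauchy frame and drops out of the deviatoric components anyway)
        epsdot = sys.v.T @ adot
        sig_ff_pk2 = sys.s_iso + sys.c_fv * epsdot  # lam^-2 sigma_ff
        S = sys.S_e_prolate + sig_ff_pk2[:, None, None] * np.einsum(
            "ni,nj->nij", grid.f0, grid.f0)
        if sys.dE is not None:
            Cinv = np.linalg.inv(C)
            Cdot = 2.0 * np.einsum("anij,a->nij", sys.dE, adot)
            S = S + self.cfg.passive.k_vm * np.einsum(
                "nij,njk,nkl->nil", Cinv, Cdot, Cinv)
        sigma = np.einsum("nij,njk,nlk->nil", F, S, F)
        tr = np.trace(sigma, axis1=1, axis2=2) / 3.0
        dev = sigma - tr[:, None, None] * np.eye(3)
        fdef = np.einsum("nij,nj->ni", F, grid.f0)
        fdef /= np.linalg.norm(fdef, axis=1)[:, None]
        sig_ff = np.einsum("ni,nij,nj->n", fdef, dev, fdef)
        lam = sys.lam_f
        return pd.DataFrame({
            "mu0": grid.mu0, "nu0": grid.nu0,
            "sigma_mumu": dev[:, 0, 0], "sigma_nunu": dev[:, 1, 1],
            "sigma_phiphi": dev[:, 2, 2], "sigma_phinu": dev[:, 2, 1],
            "sigma_ff": sig_ff,
            "E_phiphi": E[:, 2, 2], "E_nunu": E[:, 1, 1],
            "E_nuphi": E[:, 1, 2],
            "lambda_f": lam, "L_s": lam * grid.fibers.L_s0,
        })

    # -- static passive inflation -----------------------------------------

    def static_inflate(self, pressure: float, n_ramp: int = 4,
                       tol: float = 1e-8, max_iter: int = 60):
        """Passive equilibrium under a fixed cavity pressure (activation off,
        all rates zero): solve b(a) p - g(a) = 0 by damped Newton with a
        pressure ramp for globalisation.

        Returns (KinematicState, residual_norm, fields DataFrame).
        """
        A = np.zeros(self.grid.n_nodes)
        eps0 = np.zeros(self.grid.n_nodes)

        def residual(avec, p):
            sys = assemble_balance(self.grid, KinematicState(*avec), A, eps0,
                                   self.cfg.active, self.cfg.passive,
                                   n_line=self.cfg.solver.n_line)
            return sys.b * p - sys.g, sys

        a = np.zeros(3)
        for p in np.linspace(pressure / n_ramp, pressure, n_ramp):
            for _ in range(max_iter):
                r, sys = residual(a, p)
                if np.linalg.norm(r) < tol:
                    break
                J = np.empty((3, 3))
                h = 1e-6
                for j in range(3):
                    ap = a.copy(); ap[j] += h
                    am = a.copy(); am[j] -= h
                    rp, _ = residual(ap, p)
                    rm, _ = residual(am, p)
                    J[:, j] = (rp - rm) / (2 * h)
                try:
                    step = np.linalg.solve(J, r)
                except np.linalg.LinAlgError:
                    raise RuntimeError("singular Jacobian in static inflation")
                # backtracking line search; near the finite-difference noise
                # floor of the assembled forces, accept the stalled iterate
                nr0 = np.linalg.norm(r)
                lam_ls = 1.0
                for _ in range(30):
                    trial = a - lam_ls * step
                    try:
                        rt, _ = residual(trial, p)
                    except (DomainExitError, FloatingPointError):
                        lam_ls /= 2
                        continue
                    if np.linalg.norm(rt) < nr0:
                        a = trial
                        break
                    lam_ls /= 2
                else:
                    if nr0 < 10.0 * tol:
                        break
                    raise RuntimeError(
                        f"static inflation line search stalled at p={p}, "
                        f"residual {nr0:.2e}")
        r, sys = residual(a, pressure)
        state = KinematicState(*a)
        diag = {"sys": sys, "adot": np.zeros(3), "p": pressure}
        return state, float(np.linalg.norm(r)), self._field_snapshot(diag)


# ---------------------------------------------------------------------------
# module-level conveniences


def run_cycles(config: ModelConfig | None = None, n_cycles: int | None = None
               ) -> SimulationResult:
    return Simulator(config).run(n_cycles)


def static_inflate(config: ModelConfig, pressure: float, **kw):
    return Simulator(config).static_inflate(pressure, **kw)


def shapes_experiment(base: ModelConfig | None = None, n_cycles: int = 12,
                      nu_up: float | None = None) -> dict:
    """Run the matched-volume shape comparison (spherical / normal /
    ellipsoidal).  If ``nu_up`` is given, each shape is rebuilt with that
    basal truncation while preserving cavity and wall volumes."""
    from .config import ModelConfig as MC
    from .geometry import SHAPE_PRESETS

    results = {}
    for name, geom in SHAPE_PRESETS.items():
        if nu_up is not None:
            geom = build_matched_shape(geom.cavity_volume0(),
                                       geom.wall_volume0(), geom.a0, nu_up)
        cfg = base or MC()
        import copy
        cfg = copy.deepcopy(cfg)
        cfg.geometry = geom
        results[name] = Simulator(cfg).run(n_cycles)
    return results


def stroke_work_spread(results: dict, cycles=range(6, 12)) -> float:
    """(max - min)/mean of converged-cycle stroke work across shapes, in %."""
    vals = []
    for res in results.values():
        w = res.work
        vals.append(float(w[w["cycle"].isin(cycles)]["stroke_work"].mean()))
    vals = np.array(vals)
    return float((vals.max() - vals.min()) / vals.mean() * 100.0)


def sensitivity_sweep(base: ModelConfig | None = None, fraction: float = 0.2,
                      n_cycles: int = 12) -> pd.DataFrame:
    """Re-run the three-shape experiment with passive, active and circulatory
    parameter groups scaled by 1 +/- fraction; report per-run mean stroke
    work and the across-shape spread."""
    import copy
    from .circulation import CirculationParams
    from .constitutive import ActiveParams, PassiveParams
    from .config import ModelConfig as MC

    def scaled(cfg, group, f):
        cfg = copy.deepcopy(cfg)
        if group == "passive":
            d = cfg.passive.__dict__ | {"c1": cfg.passive.c1 * f}
            cfg.passive = PassiveParams(**d)
        elif group == "active":
            d = cfg.active.__dict__ | {"F0": cfg.active.F0 * f}
            cfg.active = ActiveParams(**d)
        elif group == "circulation":
            d = cfg.circulation.__dict__ | {
                "R_SYST": cfg.circulation.R_SYST * f,
                "R_PULM": cfg.circulation.R_PULM * f,
            }
            cfg.circulation = CirculationParams(**d)
        return cfg

    rows = []
    base = base or MC()
    factors = [1.0] if fraction == 0 else [1.0 - fraction, 1.0 + fraction]
    for group in ("passive", "active", "circulation"):
        for f in factors:
            try:
                res = shapes_experiment(scaled(base, group, f),
                                        n_cycles=n_cycles)
                spread = stroke_work_spread(
                    res, cycles=range(max(1, n_cycles // 2), n_cycles))
                sw = np.mean([r.work["stroke_work"].iloc[-1]
                              for r in res.values()])
                rows.append((group, f, sw, spread, "ok"))
            except Exception as e:  # individual failures logged, not fatal
                rows.append((group, f, np.nan, np.nan, f"failed: {e}"))
    return pd.DataFrame(rows, columns=["group", "factor", "stroke_work_J",
                                       "shape_spread_pct", "status"])
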