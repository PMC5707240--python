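"""Weak-form force balance reduced to three generalized equations.

The virtual-work statement contracted with dE/da_i (i = 1..3) over the wall
gives three scalar equations.  Splitting the total PK2 stress into a
rate-independent part (elastic + isometric active) and a part linear in the
kinematic rates (viscosity + force-velocity) yields

    M(a, t) adot = b(a) p - g(a, t)

where p is the uniform cavity pressure.  The incompressibility reaction
stress does no work in a volume-preserving motion and is omitted.

The internal integrals use 2-D composite Simpson quadrature on a regular
(default 9 x 11) mesh over [mu_in0, mu_out0] x [nu_up, pi]; axisymmetry
supplies a factor 2 pi.  The external-work coefficients b_i combine the
endocardial pressure line integral with the work done by the cavity pressure
on the flat basal closure disk as it translates axially with the basal
endocardial edge; integration by parts shows this combination equals the
cavity-volume gradient dV/da_i, so b3 = 0 (torsion is volume neutral).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constitutive as cst
from .geometry import (KinematicState, MappingWorkspace, ReferenceGeometry,
                       _simpson_weights, symmetric_inv_3x3)
from .fibers import FiberField, fiber_angle, fiber_basis

__all__ = ["QuadratureGrid", "GeneralizedSystem", "assemble_balance",
           "external_virtual_work", "internal_virtual_work"]


@dataclass
class QuadratureGrid:
    """Simpson quadrature mesh with cached reference-configuration data.

    nodes are a regular n_mu x n_nu product grid (odd counts in both
    directions); per-node caches: weights w (including the 2 pi factor is
    NOT included -- it is applied in the integrals), reference Jacobian J0,
    fiber rotation Q and reference fiber direction f0.
    """

    geom: ReferenceGeometry
    fibers: FiberField = field(default_factory=FiberField)
    n_mu: int = 9
    n_nu: int = 11

    def __post_init__(self):
        if self.n_mu % 2 == 0 or self.n_nu % 2 == 0:
            raise ValueError("Simpson quadrature needs odd node counts")
        g = self.geom
        mu0 = np.linspace(g.mu_in0, g.mu_out0, self.n_mu)
        nu0 = np.linspace(g.nu_up, np.pi, self.n_nu)
        wm = _simpson_weights(self.n_mu, mu0[1] - mu0[0])
        wn = _simpson_weights(self.n_nu, nu0[1] - nu0[0])
        M, N = np.meshgrid(mu0, nu0, indexing="ij")
        self.mu0 = M.ravel()
        self.nu0 = N.ravel()
        self.w = np.outer(wm, wn).ravel()
        sh, sn = np.sinh(self.mu0), np.sin(self.nu0)
        self.J0 = g.a0**3 * sh * sn * (sh**2 + sn**2)
        self.psi_star = fiber_angle(self.mu0, self.nu0, g, self.fibers)
        self.Q = fiber_basis(self.psi_star)
        self.QT = np.ascontiguousarray(np.transpose(self.Q, (0, 2, 1)))
        self.f0 = self.Q[..., :, 2].copy()
        self.ws = MappingWorkspace(g, self.mu0, self.nu0)
        self._line_ws = {}

    def line_workspace(self, n_line: int) -> MappingWorkspace:
        """Cached endocardial-line workspace with n_line Simpson nodes."""
        if n_line not in self._line_ws:
            nu = np.linspace(self.geom.nu_up, np.pi, n_line)
            mu0 = np.full_like(nu, self.geom.mu_in0)
            self._line_ws[n_line] = MappingWorkspace(self.geom, mu0, nu)
        return self._line_ws[n_line]

    @property
    def n_nodes(self):
        return self.mu0.size

    def area(self):
        return float(np.sum(self.w))


@dataclass
class GeneralizedSystem:
    """Coefficients of the three balance equations M adot = b p - g, plus the
    cavity-volume gradient dV/da (dVda) and per-node diagnostics needed for
    work accounting."""

    M: np.ndarray           # (3, 3)
    g: np.ndarray           # (3,)
    b: np.ndarray           # (3,)
    dVda: np.ndarray        # (3,)
    V: float
    g_elastic: np.ndarray   # (3,)  rate-independent elastic part of g
    M_visc: np.ndarray      # (3, 3) viscous part of M
    # per-node quantities for power bookkeeping
    v: np.ndarray           # (3, N) d eps_f / d a_i
    s_iso: np.ndarray       # (N,)   isometric active PK2 fiber coefficient
    c_fv: np.ndarray        # (N,)   force-velocity PK2 coefficient
    wJ0: np.ndarray         # (N,)   quadrature weight x reference Jacobian
    kin: dict               # deformation arrays at the nodes
    dE: np.ndarray          # (3, N, 3, 3) strain derivatives
    lam_f: np.ndarray
    A: np.ndarray
    S_e_prolate: np.ndarray  # (N, 3, 3)

    def fiber_power(self, adot):
        """Integral of S_f : Edot over the wall (kPa cm^3/s = mW)."""
        epsdot = self.v.T @ adot
        sig = (self.s_iso + self.c_fv * epsdot) * epsdot
        return 2.0 * np.pi * float(np.sum(self.wJ0 * sig))

    def viscous_power(self, adot):
        return float(adot @ self.M_visc @ adot)

    def elastic_power(self, adot):
        return float(self.g_elastic @ adot)


def internal_virtual_work(grid: QuadratureGrid, state: KinematicState, A,
                          eps_f_ed, active: cst.ActiveParams,
                          passive: cst.PassiveParams, fd_step: float = 1e-5):
    """Rate-independent generalized force g and rate-coefficient matrix M.

    ``A`` is the per-node activation level and ``eps_f_ed`` the per-node
    end-diastolic fiber strain.  Returns pieces reused by assemble_balance.
    """
    ws = grid.ws
    kin = ws.tensors(state.a1, state.a2, state.a3)
    dE = ws.strain_derivs(state.a1, state.a2, state.a3, kin, h=fd_step)
    wJ0 = grid.w * grid.J0

    # passive elastic stress (fiber frame -> prolate)
    Q, QT = grid.Q, grid.QT
    E_fib = QT @ kin["E"] @ Q
    S_e_fib = cst.passive_elastic_stress(E_fib, passive)
    S_e = Q @ S_e_fib @ QT

    # fiber kinematics
    f0 = grid.f0
    Cf = (kin["C"] @ f0[:, :, None])[:, :, 0]
    lam2 = np.sum(f0 * Cf, axis=1)
    lam = np.sqrt(lam2)
    L_s = lam * grid.fibers.L_s0
    G = cst.length_tension(L_s, active)

    # v_i = f0 . dE/da_i . f0  (so that d eps_f/dt = v . adot)
    v = np.sum(f0 * (dE @ f0[None, :, :, None])[..., 0], axis=2)

    # active PK2 coefficients: S_f = lam^-2 sigma_ff f0 (x) f0, and
    # dE_i : f0(x)f0 = v_i, so the contractions collapse to scalars
    starling = 1.0 + active.k * eps_f_ed
    s_iso = A * G * active.F0 * starling / lam2
    c_fv = A * G * active.k_av * starling / lam2

    g_elastic = 2.0 * np.pi * (dE.reshape(3, -1)
                               @ (wJ0[:, None, None] * S_e).reshape(-1))
    g_fiber = 2.0 * np.pi * np.sum(v * (wJ0 * s_iso), axis=1)
    g_vec = g_elastic + g_fiber

    # viscous: S_v = 2 k_vm Cinv dE_j Cinv adot_j
    Cinv = symmetric_inv_3x3(kin["C"])
    X = Cinv[None] @ dE @ Cinv[None]
    M_visc = 2.0 * passive.k_vm * 2.0 * np.pi * (
        (dE * wJ0[None, :, None, None]).reshape(3, -1) @ X.reshape(3, -1).T)
    M_fv = 2.0 * np.pi * ((v * (wJ0 * c_fv)) @ v.T)
    M = M_visc + M_fv

    return M, g_vec, dict(kin=kin, dE=dE, wJ0=wJ0, v=v, s_iso=s_iso,
                          c_fv=c_fv, lam=lam, S_e=S_e, g_elastic=g_elastic,
                          M_visc=M_visc)


def external_virtual_work(geom: ReferenceGeometry, state: KinematicState,
                          n_line: int = 81, h: float = 1e-6,
                          ws: MappingWorkspace | None = None):
    """External-work coefficients b (per unit cavity pressure) and the cavity
    volume and its gradient.

    b_i = endocardial pressure line integral + basal-disk work term
        = 2 pi int r (-z' dr/da_i + r' dz/da_i) d nu  +  pi r_e^2 dz_e/da_i

    evaluated by Simpson quadrature on n_line nu0 nodes; da_i derivatives of
    the endocardial curve by central differences (a3 contributes nothing:
    torsion moves points azimuthally, normal to the pressure traction).
    Analytically b = dV/da; both are returned so the balance and the flow
    constraint use consistent quantities while stroke work can be audited
    against the independently integrated volume.
    """
    if ws is None:
        nu = np.linspace(geom.nu_up, np.pi, n_line)
        ws = MappingWorkspace(geom, np.full_like(nu, geom.mu_in0), nu)
    w = _simpson_weights(ws.nu0.size, ws.nu0[1] - ws.nu0[0])
    r, z, dr, dz = ws.endocardial_curve(state.a1, state.a2)
    c_base = ws.c_warm
    V = float(np.sum(w * np.pi * r**2 * (-dz)))

    b = np.zeros(3)
    dVda = np.zeros(3)
    for i, (d1, d2) in enumerate(((h, 0.0), (0.0, h))):
        rp, zp, _, dzp = ws.endocardial_curve(state.a1 + d1, state.a2 + d2,
                                              c_init=c_base)
        rm, zm, _, dzm = ws.endocardial_curve(state.a1 - d1, state.a2 - d2,
                                              c_init=c_base)
        ra = (rp - rm) / (2.0 * h)
        za = (zp - zm) / (2.0 * h)
        endo = 2.0 * np.pi * np.sum(w * r * (-dz * ra + dr * za))
        disk = np.pi * r[0] ** 2 * za[0]
        b[i] = endo + disk
        Vp = float(np.sum(w * np.pi * rp**2 * (-dzp)))
        Vm = float(np.sum(w * np.pi * rm**2 * (-dzm)))
        dVda[i] = (Vp - Vm) / (2.0 * h)
    ws.c_warm = c_base
    return b, dVda, V


def assemble_balance(grid: QuadratureGrid, state: KinematicState, A, eps_f_ed,
                     active: cst.ActiveParams, passive: cst.PassiveParams,
                     n_line: int = 81) -> GeneralizedSystem:
    """Assemble M, g, b at the current state so that M adot = b p - g are the
    three equilibrium equations."""
    M, g_vec, pieces = internal_virtual_work(grid, state, A, eps_f_ed,
                                             active, passive)
    b, dVda, V = external_virtual_work(grid.geom, state, n_line=n_line,
                                       ws=grid.line_workspace(n_line))
    return GeneralizedSystem(
        M=M, g=g_vec, b=b, dVda=dVda, V=V,
        g_elastic=pieces["g_elastic"], M_visc=pieces["M_visc"],
        v=pieces["v"], s_iso=pieces["s_iso"], c_fv=pieces["c_fv"],
        wJ0=pieces["wJ0"], kin=pieces["kin"], dE=pieces["dE"],
        lam_f=pieces["lam"],
        A=np.asarray(A, dtype=float), S_e_prolate=pieces["S_e"],
    )
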