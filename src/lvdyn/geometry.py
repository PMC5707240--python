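"""Prolate-spheroidal geometry and the volume-preserving deformation family.

The left-ventricular wall is modelled as a truncated thick-walled prolate
spheroid.  In prolate spheroidal coordinates (mu, nu, phi) with interfocal
half-distance ``a``::

    x = a sinh(mu) sin(nu) cos(phi)
    y = a sinh(mu) sin(nu) sin(phi)
    z = a cosh(mu) cos(nu)

The reference wall occupies mu_in0 <= mu0 <= mu_out0, nu_up <= nu0 <= pi.
Deformation is described by three time-dependent parameters:

* ``a1`` -- elongation: the interfocal half-distance becomes a = a0 + a1;
* ``a2`` -- contraction/expansion of the inner surface;
* ``a3`` -- torsion, linear in (cos nu0 - cos nu_up) so that it vanishes at
  the base and is regular at the apex.

Given (a1, a2) the deformed radial coordinate mu is defined implicitly by a
cubic in cosh(mu) chosen so that the mapping preserves the volume of every
material element exactly (det F = 1).  nu and the material identity of points
are unchanged (nu = nu0).

All heavy routines are vectorised over arrays of material points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ReferenceGeometry",
    "KinematicState",
    "DomainExitError",
    "prolate_to_cartesian",
    "jacobian_determinant",
    "solve_mapped_mu",
    "torsion_phi",
    "deformation_tensors",
    "strain_derivatives",
    "cavity_volume",
    "wall_volume",
    "material_wall_volume",
    "volume_gradient",
    "build_matched_shape",
    "SHAPE_PRESETS",
]


class DomainExitError(RuntimeError):
    """The requested deformation maps material points out of the admissible
    domain (no root mu > 0 of the implicit mapping exists)."""


@dataclass(frozen=True)
class ReferenceGeometry:
    """Undeformed truncated prolate-spheroidal wall.

    Parameters
    ----------
    a0 : float
        Interfocal half-distance (cm).
    mu_in0, mu_out0 : float
        Radial coordinates of the endocardial / epicardial surfaces.
    nu_up : float
        Basal truncation angle (rad); the wall spans nu_up <= nu0 <= pi.
    """

    a0: float
    mu_in0: float
    mu_out0: float
    nu_up: float

    def __post_init__(self):
        if not (0.0 < self.mu_in0 < self.mu_out0):
            raise ValueError("need 0 < mu_in0 < mu_out0")
        if not (0.0 < self.nu_up < np.pi):
            raise ValueError("need 0 < nu_up < pi")
        if self.a0 <= 0:
            raise ValueError("need a0 > 0")

    # closed forms for the reference configuration -------------------------

    @property
    def _sin3_integral(self) -> float:
        """int_{nu_up}^{pi} sin^3(nu) d nu."""
        c = np.cos(self.nu_up)
        return 2.0 / 3.0 + c - c**3 / 3.0

    def cavity_volume0(self) -> float:
        """Reference cavity volume (cm^3): solid of revolution bounded by the
        endocardium, closed flat at the basal endocardial edge."""
        m = self.mu_in0
        return np.pi * self.a0**3 * np.sinh(m) ** 2 * np.cosh(m) * self._sin3_integral

    def wall_volume0(self) -> float:
        """Reference wall volume (cm^3): epicardial solid of revolution minus
        the cavity (the construction that reproduces the tabulated values)."""
        m = self.mu_out0
        epi = np.pi * self.a0**3 * np.sinh(m) ** 2 * np.cosh(m) * self._sin3_integral
        return epi - self.cavity_volume0()


@dataclass
class KinematicState:
    """The three deformation parameters and (optionally) their rates.

    a1 : elongation (cm), a2 : contraction (cm), a3 : torsion (rad).
    """

    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    da1: float = 0.0
    da2: float = 0.0
    da3: float = 0.0

    @property
    def a(self):
        return np.array([self.a1, self.a2, self.a3])

    @property
    def rates(self):
        return np.array([self.da1, self.da2, self.da3])


# ---------------------------------------------------------------------------
# coordinates


def prolate_to_cartesian(a, mu, nu, phi):
    """Map prolate spheroidal (mu, nu, phi) with half-distance ``a`` to
    Cartesian (x, y, z)."""
    sh, ch = np.sinh(mu), np.cosh(mu)
    sn, cn = np.sin(nu), np.cos(nu)
    return a * sh * sn * np.cos(phi), a * sh * sn * np.sin(phi), a * ch * cn


def scale_factors(a, mu, nu):
    """(g_mu, g_nu, g_phi) of the prolate spheroidal coordinates."""
    g = a * np.sqrt(np.sinh(mu) ** 2 + np.sin(nu) ** 2)
    return g, g, a * np.sinh(mu) * np.sin(nu)


def jacobian_determinant(a, mu, nu):
    """|J| = a^3 sinh(mu) sin(nu) (sinh^2 mu + sin^2 nu)."""
    return a**3 * np.sinh(mu) * np.sin(nu) * (np.sinh(mu) ** 2 + np.sin(nu) ** 2)


# ---------------------------------------------------------------------------
# the implicit volume-preserving mapping


def _mapping_rhs_terms(geom: ReferenceGeometry, mu0, nu0):
    """Split the right-hand side of the implicit relation into the part
    independent of a2 and the coefficient of a2 (it is linear in a2)."""
    a0 = geom.a0
    q = np.cos(nu0) ** 2
    c0 = np.cosh(mu0)
    cin = np.cosh(geom.mu_in0)
    r0 = a0**3 * (c0 * (c0**2 / 3.0 - q) - (1.0 / 3.0 - q))
    r1 = a0**2 * (cin * (cin**2 / 3.0 - q) - (1.0 / 3.0 - q))
    return r0, r1, q


def _solve_c(geom, state, mu0, nu0, c_init=None):
    """Solve the cubic c^3/3 - q c = T for c = cosh(mu) >= 1 on the physical
    branch (continuous with c = cosh mu0 at zero deformation).

    Safeguarded vectorised Newton: the residual is strictly increasing in c
    for c > sqrt(q), so the physical root is unique.
    """
    a = geom.a0 + state.a1
    if a <= 0:
        raise DomainExitError("a0 + a1 must be positive")
    r0, r1, q = _mapping_rhs_terms(geom, mu0, nu0)
    T = (r0 - state.a2 * r1) / a**3 + (1.0 / 3.0 - q)

    lo = np.maximum(1.0, np.sqrt(q)) * (1.0 + 1e-14)
    flo = lo**3 / 3.0 - q * lo - T
    if np.any(flo > 1e-12 * np.maximum(1.0, np.abs(T))):
        raise DomainExitError(
            "deformation too extreme: implicit mapping has no root with mu > 0"
        )

    c = np.array(c_init if c_init is not None else np.cosh(mu0), dtype=float)
    c = np.maximum(c, lo)
    for _ in range(100):
        f = c**3 / 3.0 - q * c - T
        fp = c**2 - q
        step = f / np.maximum(fp, 1e-300)
        c_new = np.maximum(c - step, lo)
        if np.max(np.abs(c_new - c)) < 1e-14 * np.max(c_new):
            c = c_new
            break
        c = c_new
    return c, q, r0, r1, a


def solve_mapped_mu(geom: ReferenceGeometry, state: KinematicState, mu0, nu0,
                    c_init=None):
    """Deformed radial coordinate and its partials.

    Returns ``(mu, dmu_dmu0, dmu_dnu0)`` where the partial derivatives are
    obtained by implicit differentiation of the mapping relation.
    """
    mu0 = np.asarray(mu0, dtype=float)
    nu0 = np.asarray(nu0, dtype=float)
    c, q, r0, r1, a = _solve_c(geom, state, mu0, nu0, c_init)
    sh = np.sqrt(np.maximum(c**2 - 1.0, 0.0))
    if np.any(sh <= 0):
        raise DomainExitError("mapped mu reached zero")
    mu = np.arccosh(c)

    a0 = geom.a0
    c0, cin = np.cosh(mu0), np.cosh(geom.mu_in0)
    dG_dc = a**3 * (c**2 - q)

    # d/dmu0 of the RHS at fixed nu0
    dR_dmu0 = a0**3 * np.sinh(mu0) * (c0**2 - q)
    dc_dmu0 = dR_dmu0 / dG_dc

    # q-derivatives: LHS contributes a^3 (1 - c); RHS contributes
    # a0^2 [a0 (1 - c0) - a2 (1 - cin)]
    dq_dnu0 = -np.sin(2.0 * nu0)
    dR_dq = a0**2 * (a0 * (1.0 - c0) - state.a2 * (1.0 - cin))
    dLHS_dq = a**3 * (1.0 - c)
    dc_dnu0 = -(dLHS_dq - dR_dq) * dq_dnu0 / dG_dc

    return mu, dc_dmu0 / sh, dc_dnu0 / sh


def torsion_phi(state: KinematicState, nu0, phi0, nu_up):
    """Azimuthal coordinate after torsion: phi = phi0 + a3 (cos nu0 - cos nu_up)."""
    return phi0 + state.a3 * (np.cos(nu0) - np.cos(nu_up))


# ---------------------------------------------------------------------------
# deformation tensors


def deformation_tensors(geom: ReferenceGeometry, state: KinematicState, mu0, nu0,
                        c_init=None):
    """F, C and E in orthonormal prolate-spheroidal components at material
    points (mu0, nu0).

    Rows of F refer to the deformed basis (e_mu, e_nu, e_phi), columns to the
    reference basis.  Returns a dict with keys ``mu, dmu_dmu0, dmu_dnu0, F, C,
    E, detF``; arrays are stacked over the leading point axis.
    """
    mu0 = np.atleast_1d(np.asarray(mu0, dtype=float))
    nu0 = np.atleast_1d(np.asarray(nu0, dtype=float))
    mu, dmm, dmn = solve_mapped_mu(geom, state, mu0, nu0, c_init)

    a = geom.a0 + state.a1
    a0 = geom.a0
    sh, ch = np.sinh(mu), np.cosh(mu)
    sh0, ch0 = np.sinh(mu0), np.cosh(mu0)
    sn, cn = np.sin(nu0), np.cos(nu0)

    g = a * np.sqrt(sh**2 + sn**2)
    g0 = a0 * np.sqrt(sh0**2 + sn**2)
    gphi = a * sh * sn
    gphi0 = a0 * sh0 * sn

    n = mu0.shape[0]
    F = np.zeros((n, 3, 3))
    F[:, 0, 0] = g * dmm / g0
    F[:, 0, 1] = g * dmn / g0
    F[:, 1, 1] = g / g0
    F[:, 2, 1] = gphi * (-state.a3 * sn) / g0
    with np.errstate(invalid="ignore", divide="ignore"):
        F[:, 2, 2] = np.where(sn > 0, gphi / np.where(sn > 0, gphi0, 1.0), sh / sh0)

    C = np.einsum("nki,nkj->nij", F, F)
    E = 0.5 * (C - np.eye(3))
    detF = F[:, 0, 0] * F[:, 1, 1] * F[:, 2, 2]
    return {
        "mu": mu, "dmu_dmu0": dmm, "dmu_dnu0": dmn,
        "F": F, "C": C, "E": E, "detF": detF,
    }


def strain_derivatives(geom, state, mu0, nu0, h=1e-5, c_init=None, base=None):
    """dE/da_i for i = 1, 2, 3, shape (3, n, 3, 3).

    a1 and a2 enter through the implicit mapping and are differentiated by
    central finite differences (the mapping re-solve is cheap and the formula
    is validated against Richardson-extrapolated differences in the tests);
    the torsion derivative dE/da3 is analytic because a3 enters F through a
    single component, linearly.
    """
    mu0 = np.atleast_1d(np.asarray(mu0, dtype=float))
    nu0 = np.atleast_1d(np.asarray(nu0, dtype=float))
    if base is None:
        base = deformation_tensors(geom, state, mu0, nu0, c_init)
    n = mu0.shape[0]
    dE = np.empty((3, n, 3, 3))

    for i, name in enumerate(("a1", "a2")):
        sp = KinematicState(state.a1, state.a2, state.a3)
        sm = KinematicState(state.a1, state.a2, state.a3)
        setattr(sp, name, getattr(state, name) + h)
        setattr(sm, name, getattr(state, name) - h)
        Ep = deformation_tensors(geom, sp, mu0, nu0, c_init)["E"]
        Em = deformation_tensors(geom, sm, mu0, nu0, c_init)["E"]
        dE[i] = (Ep - Em) / (2.0 * h)

    # analytic in a3: only F[2,1] = -gphi a3 sin(nu0) / g0 depends on a3
    a = geom.a0 + state.a1
    sn = np.sin(nu0)
    sh0 = np.sinh(mu0)
    g0 = geom.a0 * np.sqrt(sh0**2 + sn**2)
    gphi = a * np.sinh(base["mu"]) * sn
    dF = np.zeros((n, 3, 3))
    dF[:, 2, 1] = -gphi * sn / g0
    F = base["F"]
    dC = np.einsum("nki,nkj->nij", dF, F) + np.einsum("nki,nkj->nij", F, dF)
    dE[2] = 0.5 * dC
    return dE


class MappingWorkspace:
    """Cached per-point constants of the implicit mapping for repeated solves
    at fixed material points (the quadrature grid and boundary lines).

    The right-hand side of the implicit relation is linear in a2 and its
    coefficients depend only on (mu0, nu0), so they are precomputed once;
    each state evaluation then costs a handful of vectorised Newton steps.
    """

    def __init__(self, geom: ReferenceGeometry, mu0, nu0):
        self.geom = geom
        self.mu0 = np.asarray(mu0, dtype=float)
        self.nu0 = np.asarray(nu0, dtype=float)
        self.r0, self.r1, self.q = _mapping_rhs_terms(geom, self.mu0, self.nu0)
        self.c0 = np.cosh(self.mu0)
        self.sh0 = np.sinh(self.mu0)
        self.sn = np.sin(self.nu0)
        self.cn = np.cos(self.nu0)
        self.lo = np.maximum(1.0, np.sqrt(self.q)) * (1.0 + 1e-14)
        self.dq_dnu0 = -np.sin(2.0 * self.nu0)
        self.dR_dmu0 = geom.a0**3 * self.sh0 * (self.c0**2 - self.q)
        self.g0 = geom.a0 * np.sqrt(self.sh0**2 + self.sn**2)
        self.gphi0 = geom.a0 * self.sh0 * self.sn
        self.cin = np.cosh(geom.mu_in0)
        self.c_warm = self.c0.copy()

    def solve(self, a1, a2, c_init=None):
        """cosh(mu) on the physical branch (fixed-point cost, safeguarded)."""
        a = self.geom.a0 + a1
        if a <= 0:
            raise DomainExitError("a0 + a1 must be positive")
        a3cube = a**3
        q, lo = self.q, self.lo
        T = (self.r0 - a2 * self.r1) / a3cube + (1.0 / 3.0 - q)
        flo = lo**3 / 3.0 - q * lo - T
        if np.any(flo > 1e-12 * np.maximum(1.0, np.abs(T))):
            raise DomainExitError(
                "deformation too extreme: implicit mapping has no root with mu > 0")
        c = self.c_warm if c_init is None else np.asarray(c_init, dtype=float)
        c = np.maximum(c, lo)
        for _ in range(3):
            cc = c * c
            c = np.maximum(c - (c * (cc / 3.0 - q) - T) / (cc - q), lo)
        # safeguarded polish for stragglers (warm starts converge in 2-3)
        for _ in range(60):
            cc = c * c
            step = (c * (cc / 3.0 - q) - T) / (cc - q)
            if np.max(np.abs(step)) < 1e-14 * np.max(c):
                break
            c = np.maximum(c - step, lo)
        return c, a

    def derivs(self, c, a, a2):
        """(sinh mu, dmu/dmu0, dmu/dnu0) by implicit differentiation."""
        sh = np.sqrt(c**2 - 1.0)
        if np.any(sh <= 0):
            raise DomainExitError("mapped mu reached zero")
        dG_dc = a**3 * (c**2 - self.q)
        dc_dmu0 = self.dR_dmu0 / dG_dc
        a0 = self.geom.a0
        dR_dq = a0**2 * (a0 * (1.0 - self.c0) - a2 * (1.0 - self.cin))
        dc_dnu0 = -(a**3 * (1.0 - c) - dR_dq) * self.dq_dnu0 / dG_dc
        return sh, dc_dmu0 / sh, dc_dnu0 / sh

    def tensors(self, a1, a2, a3, c_init=None):
        """F, C, E (and mapping data) at all cached points for one state."""
        c, a = self.solve(a1, a2, c_init)
        self.c_warm = c
        sh, dmm, dmn = self.derivs(c, a, a2)
        sn = self.sn
        g = a * np.sqrt(sh**2 + sn**2)
        gphi = a * sh * sn
        n = c.shape[0]
        F = np.zeros((n, 3, 3))
        F[:, 0, 0] = g * dmm / self.g0
        F[:, 0, 1] = g * dmn / self.g0
        F[:, 1, 1] = g / self.g0
        F[:, 2, 1] = gphi * (-a3 * sn) / self.g0
        with np.errstate(invalid="ignore", divide="ignore"):
            F[:, 2, 2] = np.where(sn > 0, gphi / np.where(sn > 0, self.gphi0, 1.0),
                                  sh / self.sh0)
        C = np.matmul(np.transpose(F, (0, 2, 1)), F)
        E = 0.5 * (C - np.eye(3))
        return {"c": c, "mu": np.arccosh(c), "sh": sh, "dmu_dmu0": dmm,
                "dmu_dnu0": dmn, "F": F, "C": C, "E": E, "a": a,
                "detF": F[:, 0, 0] * F[:, 1, 1] * F[:, 2, 2]}

    def strain_derivs(self, a1, a2, a3, base, h=1e-5):
        """dE/da_i, shape (3, n, 3, 3): central differences in a1, a2
        (re-solving the cached mapping), analytic in a3."""
        dE = np.empty((3,) + base["E"].shape)
        for i, (d1, d2) in enumerate(((h, 0.0), (0.0, h))):
            Ep = self.tensors(a1 + d1, a2 + d2, a3, c_init=base["c"])["E"]
            Em = self.tensors(a1 - d1, a2 - d2, a3, c_init=base["c"])["E"]
            dE[i] = (Ep - Em) / (2.0 * h)
        self.c_warm = base["c"]
        n = base["E"].shape[0]
        dF = np.zeros((n, 3, 3))
        gphi = base["a"] * base["sh"] * self.sn
        dF[:, 2, 1] = -gphi * self.sn / self.g0
        F = base["F"]
        dC = (np.matmul(np.transpose(dF, (0, 2, 1)), F)
              + np.matmul(np.transpose(F, (0, 2, 1)), dF))
        dE[2] = 0.5 * dC
        return dE

    def endocardial_curve(self, a1, a2, c_init=None):
        """(r, z, dr/dnu, dz/dnu) along the cached (endocardial) line."""
        c, a = self.solve(a1, a2, c_init)
        self.c_warm = c
        sh, _, dmn = self.derivs(c, a, a2)
        r = a * sh * self.sn
        z = a * c * self.cn
        dr = a * (c * dmn * self.sn + sh * self.cn)
        dz = a * (sh * dmn * self.cn - c * self.sn)
        return r, z, dr, dz


def symmetric_inv_3x3(C):
    """Inverse of a stack of symmetric 3x3 matrices with C[0,2] = 0 (the
    structure of the right Cauchy-Green tensor of this deformation family)."""
    c00, c01, c11 = C[:, 0, 0], C[:, 0, 1], C[:, 1, 1]
    c12, c22 = C[:, 1, 2], C[:, 2, 2]
    # adjugate of [[c00,c01,0],[c01,c11,c12],[0,c12,c22]]
    a00 = c11 * c22 - c12 * c12
    a01 = -(c01 * c22)
    a02 = c01 * c12
    a11 = c00 * c22
    a12 = -(c00 * c12)
    a22 = c00 * c11 - c01 * c01
    det = c00 * a00 + c01 * a01
    inv = np.empty_like(C)
    inv[:, 0, 0] = a00
    inv[:, 0, 1] = inv[:, 1, 0] = a01
    inv[:, 0, 2] = inv[:, 2, 0] = a02
    inv[:, 1, 1] = a11
    inv[:, 1, 2] = inv[:, 2, 1] = a12
    inv[:, 2, 2] = a22
    inv /= det[:, None, None]
    return inv


# ---------------------------------------------------------------------------
# volumes


def _simpson_weights(n, h):
    if n % 2 == 0:
        raise ValueError("Simpson rule needs an odd number of nodes")
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * h / 3.0


def _endocardial_curve(geom, state, nu, c_init=None):
    """(r, z, dr/dnu, dz/dnu) along the deformed endocardium."""
    mu0 = np.full_like(nu, geom.mu_in0)
    mu, _, dmn = solve_mapped_mu(geom, state, mu0, nu, c_init)
    a = geom.a0 + state.a1
    sh, ch = np.sinh(mu), np.cosh(mu)
    sn, cn = np.sin(nu), np.cos(nu)
    r = a * sh * sn
    z = a * ch * cn
    dr = a * (ch * dmn * sn + sh * cn)
    dz = a * (sh * dmn * cn - ch * sn)
    return r, z, dr, dz


def cavity_volume(geom: ReferenceGeometry, state: KinematicState | None = None,
                  n_nodes: int = 81):
    """LV cavity volume (cm^3): solid of revolution about the z axis bounded
    by the deformed endocardium from the apex to nu0 = nu_up, closed flat at
    the basal endocardial edge.  Composite Simpson quadrature in nu0."""
    if state is None:
        state = KinematicState()
    nu = np.linspace(geom.nu_up, np.pi, n_nodes)
    w = _simpson_weights(n_nodes, nu[1] - nu[0])
    r, _, _, dz = _endocardial_curve(geom, state, nu)
    return float(np.sum(w * np.pi * r**2 * (-dz)))


def wall_volume(geom: ReferenceGeometry, state: KinematicState | None = None,
                n_nodes: int = 81):
    """Wall volume (cm^3): epicardial solid of revolution minus the cavity."""
    if state is None:
        state = KinematicState()
    nu = np.linspace(geom.nu_up, np.pi, n_nodes)
    w = _simpson_weights(n_nodes, nu[1] - nu[0])
    mu0 = np.full_like(nu, geom.mu_out0)
    # re-use the endocardial machinery with mu0 = mu_out0
    mu, _, dmn = solve_mapped_mu(geom, state, mu0, nu)
    a = geom.a0 + state.a1
    sh, ch = np.sinh(mu), np.cosh(mu)
    sn, cn = np.sin(nu), np.cos(nu)
    r = a * sh * sn
    dz = a * (sh * dmn * cn - ch * sn)
    epi_solid = float(np.sum(w * np.pi * r**2 * (-dz)))
    return epi_solid - cavity_volume(geom, state, n_nodes)


def material_wall_volume(geom: ReferenceGeometry, state: KinematicState | None = None,
                         n_mu: int = 33, n_nu: int = 33):
    """Volume of the mapped material wall, by integrating |J| over the
    deformed image of the wall.  The mapping is volume preserving, so this
    equals the reference value for every admissible state (used as the
    invariance oracle)."""
    if state is None:
        state = KinematicState()
    mu0 = np.linspace(geom.mu_in0, geom.mu_out0, n_mu)
    nu0 = np.linspace(geom.nu_up, np.pi, n_nu)
    wmu = _simpson_weights(n_mu, mu0[1] - mu0[0])
    wnu = _simpson_weights(n_nu, nu0[1] - nu0[0])
    M, N = np.meshgrid(mu0, nu0, indexing="ij")
    W = np.outer(wmu, wnu)
    mu, dmm, _ = solve_mapped_mu(geom, state, M.ravel(), N.ravel())
    a = geom.a0 + state.a1
    J = jacobian_determinant(a, mu, N.ravel()) * dmm
    return float(2.0 * np.pi * np.sum(W.ravel() * J))


def volume_gradient(geom, state, n_nodes: int = 81, h: float = 1e-6):
    """(dV/da1, dV/da2) of the cavity volume by central differences.
    Torsion does not change the cavity volume (dV/da3 = 0)."""
    out = np.zeros(2)
    for i, name in enumerate(("a1", "a2")):
        sp = KinematicState(state.a1, state.a2, state.a3)
        sm = KinematicState(state.a1, state.a2, state.a3)
        setattr(sp, name, getattr(state, name) + h)
        setattr(sm, name, getattr(state, name) - h)
        out[i] = (cavity_volume(geom, sp, n_nodes) -
                  cavity_volume(geom, sm, n_nodes)) / (2.0 * h)
    return out


# ---------------------------------------------------------------------------
# matched-volume shape construction


def build_matched_shape(target_cavity_volume, target_wall_volume, a0, nu_up,
                        rtol: float = 1e-10) -> ReferenceGeometry:
    """Find mu_in0, mu_out0 so that the reference cavity and wall volumes hit
    the targets (two monotone 1-D root finds on the closed forms)."""
    if target_cavity_volume <= 0 or target_wall_volume <= 0:
        raise ValueError("volume targets must be positive")
    c = np.cos(nu_up)
    i3 = 2.0 / 3.0 + c - c**3 / 3.0

    def solid(m):
        return np.pi * a0**3 * np.sinh(m) ** 2 * np.cosh(m) * i3

    def solve_mu(v):
        hi = 1.0
        while solid(hi) < v:
            hi *= 2.0
            if hi > 64:
                raise ValueError("volume target infeasible for this a0")
        return brentq(lambda m: solid(m) - v, 1e-12, hi, xtol=1e-14, rtol=1e-15)

    mu_in = solve_mu(target_cavity_volume)
    mu_out = solve_mu(target_cavity_volume + target_wall_volume)
    geom = ReferenceGeometry(a0, mu_in, mu_out, nu_up)
    if abs(geom.cavity_volume0() - target_cavity_volume) > rtol * target_cavity_volume:
        raise ValueError("matched-shape inversion failed to meet tolerance")
    return geom


#: Reference geometries with matched cavity (59.8714 cm^3) and wall
#: (158.112 cm^3) volumes, used throughout for shape experiments.
SHAPE_PRESETS = {
    "spherical": ReferenceGeometry(2.7307, 0.7470308, 1.1173771, 1.1112),
    "normal": ReferenceGeometry(4.6307, 0.39521852, 0.6719001, 1.1112),
    "ellipsoidal": ReferenceGeometry(6.7307, 0.235, 0.426, 1.1112),
}
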