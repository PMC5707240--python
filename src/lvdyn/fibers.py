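"""Helical muscle-fiber architecture on surfaces of constant mu0.

Fibers lie in surfaces of constant mu0 and wind helically according to
``phi0 = phi_b + omega (cos nu0 - cos nu_up)``, where the wrapping parameter
``omega`` depends on mu0 only.  The local fiber angle relative to the
circumferential direction is measured by psi (endocardium ~ +85 deg,
epicardium ~ -65 deg at the equator, after Streeter) or by the
quadrant-adjusted angle psi* in [0, pi):  psi* = psi for psi >= 0 and
psi + pi for psi < 0, which makes the fiber tangent field continuous across
the midwall where psi changes sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import KinematicState, ReferenceGeometry, solve_mapped_mu

__all__ = [
    "FiberField",
    "FiberStretchState",
    "equatorial_angle",
    "wrapping_parameter",
    "fiber_angle",
    "fiber_basis",
    "fiber_stretch",
]

#: sarcomere length in the reference configuration (um)
L_S0_DEFAULT = 1.82


@dataclass(frozen=True)
class FiberField:
    """Transmural helix-angle prescription.

    psi_in, psi_out : equatorial helix angles (rad) at the endocardial and
    epicardial surfaces; the equatorial angle varies linearly in mu0 between
    them.  L_s0 is the uniform reference sarcomere length (um).
    """

    psi_in: float = np.deg2rad(85.0)
    psi_out: float = np.deg2rad(-65.0)
    L_s0: float = L_S0_DEFAULT


@dataclass
class FiberStretchState:
    lambda_f: float
    L_s: float
    eps_f: float


def equatorial_angle(mu0, geom: ReferenceGeometry, field: FiberField):
    """Equatorial helix angle psi_eq(mu0): linear in mu0 from psi_in at the
    endocardium to psi_out at the epicardium."""
    mi, mo = geom.mu_in0, geom.mu_out0
    t = (np.asarray(mu0, dtype=float) - mi) / (mo - mi)
    return field.psi_in * (1.0 - t) + field.psi_out * t


def _quadrant(psi):
    """psi* in [0, pi): psi + pi when psi < 0, else psi."""
    psi = np.asarray(psi, dtype=float)
    return np.where(psi < 0, psi + np.pi, psi)


def wrapping_parameter(psi_eq_star, mu0):
    """omega = cot(psi*_eq) coth(mu0).

    psi*_eq = pi/2 gives omega = 0 (circumferentially wrapped midwall
    surface is excluded: psi*_eq = 0 means fibers are exactly circumferential
    and omega is unbounded -- that case is signalled with +/-inf)."""
    psi_eq_star = np.asarray(psi_eq_star, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    with np.errstate(divide="ignore"):
        out = (np.cos(psi_eq_star) / np.sin(psi_eq_star)) / np.tanh(mu0)
    return np.where(np.isclose(np.sin(psi_eq_star), 0.0), np.inf, out)


def fiber_angle(mu0, nu0, geom: ReferenceGeometry, field: FiberField):
    """Quadrant-adjusted fiber angle psi*(mu0, nu0) from the wrapping
    parameter:

    cos psi* = omega sinh(mu0) sin^2(nu0) /
               sqrt(sinh^2 mu0 + sin^2 nu0 + omega^2 sinh^2 mu0 sin^4 nu0)
    """
    mu0 = np.asarray(mu0, dtype=float)
    nu0 = np.asarray(nu0, dtype=float)
    om = wrapping_parameter(_quadrant(equatorial_angle(mu0, geom, field)), mu0)
    sh, sn = np.sinh(mu0), np.sin(nu0)
    circ = ~np.isfinite(om)
    om_safe = np.where(circ, 0.0, om)
    num = om_safe * sh * sn**2
    den = np.sqrt(sh**2 + sn**2 + om_safe**2 * sh**2 * sn**4)
    cos_ps = np.where(circ, np.sign(np.cos(_quadrant(equatorial_angle(mu0, geom, field)))),
                      num / den)
    return np.arccos(np.clip(cos_ps, -1.0, 1.0))


def fiber_basis(psi_star):
    """Rotation matrix Q mapping fiber-frame (s, n, f) components to prolate
    (mu, nu, phi) components, S_prolate = Q S_fiber Q^T::

        Q = [[1, 0, 0],
             [0, -cos psi*,  sin psi*],
             [0, -sin psi*, -cos psi*]]

    Columns are the s, n, f axes in the prolate basis; orthogonal with
    determinant +1.  Vectorised over psi_star (returns (..., 3, 3))."""
    psi_star = np.asarray(psi_star, dtype=float)
    c, s = np.cos(psi_star), np.sin(psi_star)
    Q = np.zeros(psi_star.shape + (3, 3))
    Q[..., 0, 0] = 1.0
    Q[..., 1, 1] = -c
    Q[..., 1, 2] = s
    Q[..., 2, 1] = -s
    Q[..., 2, 2] = -c
    return Q


def _arc_length_ratio(geom, state, field, mu0, nu0):
    """lambda_f from the ratio of deformed to reference fiber arc-length
    increments (the route through the explicit fiber paths)."""
    mu0 = np.asarray(mu0, dtype=float)
    nu0 = np.asarray(nu0, dtype=float)
    om = wrapping_parameter(_quadrant(equatorial_angle(mu0, geom, field)), mu0)
    mu, _, dmn = solve_mapped_mu(geom, state, mu0, nu0)
    a, a0 = geom.a0 + state.a1, geom.a0
    sh, sh0 = np.sinh(mu), np.sinh(mu0)
    sn = np.sin(nu0)
    circ = ~np.isfinite(om)
    if np.any(circ):
        # circumferential fibers: stretch is the ratio of circumferences
        lam_c = (a * sh) / (a0 * sh0)
    om_safe = np.where(circ, 0.0, om)
    ds = a * np.sqrt((1.0 + dmn**2) * (sh**2 + sn**2)
                     + (om_safe + state.a3) ** 2 * sh**2 * sn**4)
    ds0 = a0 * np.sqrt(sh0**2 + sn**2 + om_safe**2 * sh0**2 * sn**4)
    lam = ds / ds0
    if np.any(circ):
        lam = np.where(circ, lam_c, lam)
    return lam


def fiber_stretch(geom, state, field, mu0, nu0, via="arc"):
    """Fiber stretch ratio lambda_f, sarcomere length L_s = lambda_f L_s0 and
    fiber Green strain eps_f = (lambda_f^2 - 1)/2.

    ``via='arc'`` uses the arc-length ratio of the fiber paths;
    ``via='tensor'`` uses lambda_f^2 = f0 . C f0 with the reference fiber
    direction f0.  The two routes agree to roundoff and the tests assert it.
    """
    mu0 = np.atleast_1d(np.asarray(mu0, dtype=float))
    nu0 = np.atleast_1d(np.asarray(nu0, dtype=float))
    if via == "arc":
        lam = _arc_length_ratio(geom, state, field, mu0, nu0)
    elif via == "tensor":
        from .geometry import deformation_tensors

        psi = fiber_angle(mu0, nu0, geom, field)
        f0 = fiber_basis(psi)[..., :, 2]
        C = deformation_tensors(geom, state, mu0, nu0)["C"]
        lam = np.sqrt(np.einsum("ni,nij,nj->n", f0, C, f0))
    else:
        raise ValueError("via must be 'arc' or 'tensor'")
    return FiberStretchState(lam, lam * field.L_s0, 0.5 * (lam**2 - 1.0))
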