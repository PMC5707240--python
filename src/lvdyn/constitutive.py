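"""Constitutive laws of the myocardium.

Three stress contributions, all as second Piola-Kirchhoff (PK2) tensors:

* active fiber stress, uniaxial along the fiber: the Cauchy fiber stress is
  sigma_ff = A(t) G(L_s) (F0 + k_av d eps_f/dt) (1 + k eps_f,ed), combining a
  prescribed activation wave A, a Gaussian length-tension factor G, a linear
  force-velocity term and a Frank-Starling preload factor; the PK2 form is
  S_f = lambda_f^-2 sigma_ff e_f (x) e_f;
* passive transversely isotropic (Fung-type exponential) elasticity,
  S_e = dPsi/dE with Psi = c1 (e^W - 1)/2;
* Kelvin-Voigt matrix viscosity, S_v = k_vm C^-1 Cdot C^-1, the pull-back of
  the Newtonian viscous Cauchy stress k_vm (grad v + grad v^T).

Units: stresses kPa, lengths um (sarcomere) / cm (tissue), time s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActiveParams",
    "PassiveParams",
    "activation",
    "length_tension",
    "active_cauchy_fiber_stress",
    "strain_energy",
    "passive_elastic_stress",
    "viscous_stress",
    "total_pk2",
    "rotate_to_prolate",
]


@dataclass(frozen=True)
class ActiveParams:
    """Active contraction parameters (defaults: normal human LV).

    F0 : peak active stress scale (kPa); k_av : force-velocity coefficient
    (kPa s); k : Frank-Starling force sensitivity (-); k_prime : activation
    shape sensitivity to end-diastolic strain (-); L_smax : sarcomere length
    of maximal tension (um); L_sw : width of the length-tension peak (um);
    T_a : activation period (s); T_c : cardiac cycle period (s).
    """

    F0: float = 300.0
    k_av: float = 0.5
    k: float = 0.0
    k_prime: float = 1.0
    L_smax: float = 2.23
    L_sw: float = 0.2
    T_a: float = 0.4
    T_c: float = 1.0

    def __post_init__(self):
        if self.F0 <= 0 or self.L_sw <= 0:
            raise ValueError("F0 and L_sw must be positive")
        if not (0 < self.T_a <= self.T_c):
            raise ValueError("need 0 < T_a <= T_c")


@dataclass(frozen=True)
class PassiveParams:
    """Passive viscoelastic parameters.

    c1 : stress scale of the exponential strain-energy (kPa); b_ff, b_xx,
    b_fx : quadratic-form coefficients of fiber, cross-fiber and shear
    strains; k_vm : matrix viscosity (kPa s).
    """

    c1: float = 1.0
    b_ff: float = 5.0
    b_xx: float = 3.0
    b_fx: float = 7.0
    k_vm: float = 0.025

    def __post_init__(self):
        for v in (self.c1, self.b_ff, self.b_xx, self.b_fx, self.k_vm):
            if v < 0:
                raise ValueError("passive parameters must be nonnegative")


# ---------------------------------------------------------------------------
# active stress


def activation(t_cycle, eps_f_ed, params: ActiveParams):
    """Activation A(t) in [0, 1].

    A = [sin(pi t / T_a)]^d with d = 1/(1 + k' eps_f,ed) for 0 <= t <= T_a,
    zero for the rest of the cycle.  Larger end-diastolic strain prolongs
    activation (d < 1).  Vectorised over eps_f_ed (per material point).
    """
    t = np.asarray(t_cycle, dtype=float)
    eps = np.asarray(eps_f_ed, dtype=float)
    denom = 1.0 + params.k_prime * eps
    if np.any(denom <= 0):
        raise ValueError("pathological end-diastolic strain: 1 + k' eps <= 0")
    d = 1.0 / denom
    s = np.where((t >= 0) & (t <= params.T_a), np.sin(np.pi * t / params.T_a), 0.0)
    return np.where(s > 0, s, 0.0) ** d


def length_tension(L_s, params: ActiveParams):
    """Gaussian length-tension factor G(L_s) in (0, 1], peaked at L_smax."""
    L_s = np.asarray(L_s, dtype=float)
    return np.exp(-((L_s - params.L_smax) ** 2) / (2.0 * params.L_sw**2))


def active_cauchy_fiber_stress(A, G, deps_f_dt, eps_f_ed, params: ActiveParams,
                               clamp_nonnegative: bool = False):
    """Active Cauchy fiber stress sigma_ff (kPa).

    Not clamped by default; rapid shortening can transiently drive the
    force-velocity term negative and the caller may request a clamp."""
    s = A * G * (params.F0 + params.k_av * np.asarray(deps_f_dt)) \
        * (1.0 + params.k * np.asarray(eps_f_ed))
    if clamp_nonnegative:
        s = np.maximum(s, 0.0)
    return s


# ---------------------------------------------------------------------------
# passive elasticity


def _quadratic_form(E_fib, params: PassiveParams):
    """W(E) in the fiber frame, ordering (s, n, f)."""
    Ess, Enn, Eff = E_fib[..., 0, 0], E_fib[..., 1, 1], E_fib[..., 2, 2]
    Esn, Ens = E_fib[..., 0, 1], E_fib[..., 1, 0]
    Esf, Efs = E_fib[..., 0, 2], E_fib[..., 2, 0]
    Enf, Efn = E_fib[..., 1, 2], E_fib[..., 2, 1]
    return (params.b_ff * Eff**2
            + params.b_xx * (Enn**2 + Ess**2 + Esn**2 + Ens**2)
            + params.b_fx * (Efn**2 + Enf**2 + Efs**2 + Esf**2))


def strain_energy(E_fib, params: PassiveParams):
    """Psi = c1 (e^W - 1) / 2 (kPa)."""
    return 0.5 * params.c1 * (np.exp(_quadratic_form(E_fib, params)) - 1.0)


def passive_elastic_stress(E_fib, params: PassiveParams, w_max: float = 250.0):
    """PK2 elastic stress in the fiber frame (s, n, f):

    S_e = c1 e^W [[bxx Ess, bxx Esn, bfx Esf],
                  [bxx Ens, bxx Enn, bfx Enf],
                  [bfx Efs, bfx Efn, bff Eff]]

    which is exactly dPsi/dE.  Raises if W overflows (strain far outside the
    physiological range)."""
    E_fib = np.asarray(E_fib, dtype=float)
    W = _quadratic_form(E_fib, params)
    if np.any(W > w_max):
        raise FloatingPointError(
            "strain-energy exponent overflow: strain out of physiological range"
        )
    ew = np.exp(W)
    b = np.array([
        [params.b_xx, params.b_xx, params.b_fx],
        [params.b_xx, params.b_xx, params.b_fx],
        [params.b_fx, params.b_fx, params.b_ff],
    ])
    b = b * 0.5 + b.T * 0.5  # symmetric by construction; defensive
    return params.c1 * ew[..., None, None] * b * E_fib


# ---------------------------------------------------------------------------
# viscosity


def viscous_stress(C, Cdot, k_vm):
    """Kelvin-Voigt PK2 viscous stress S_v = k_vm C^-1 Cdot C^-1."""
    Cinv = np.linalg.inv(C)
    return k_vm * Cinv @ Cdot @ Cinv


def total_pk2(F, C, Cdot, Q, sigma_ff_active, passive: PassiveParams):
    """Total PK2 stress (prolate components) without the incompressibility
    reaction term, which does no work in a volume-preserving motion:

        S = S_e + S_f + S_v

    with S_f = lambda_f^-2 sigma_ff e_f (x) e_f, lambda_f^2 = f0 . C f0.
    Also returns the deviatoric Cauchy tensor dev(F S F^T) (det F = 1), in
    which the omitted reaction term would cancel anyway.  Vectorised over a
    leading point axis.
    """
    F, C, Cdot = np.asarray(F), np.asarray(C), np.asarray(Cdot)
    Q = np.asarray(Q)
    QT = np.swapaxes(Q, -1, -2)
    E = 0.5 * (C - np.eye(3))
    S_e = Q @ passive_elastic_stress(QT @ E @ Q, passive) @ QT
    f0 = Q[..., :, 2]
    lam2 = np.einsum("...i,...ij,...j->...", f0, C, f0)
    S_f = (np.asarray(sigma_ff_active) / lam2)[..., None, None] * np.einsum(
        "...i,...j->...ij", f0, f0)
    Cinv = np.linalg.inv(C)
    S_v = passive.k_vm * Cinv @ Cdot @ Cinv
    S = S_e + S_f + S_v
    sigma = F @ S @ np.swapaxes(F, -1, -2)
    tr = np.trace(sigma, axis1=-2, axis2=-1) / 3.0
    dev = sigma - tr[..., None, None] * np.eye(3)
    return {"S": S, "S_e": S_e, "S_f": S_f, "S_v": S_v,
            "cauchy_deviatoric": dev}


# ---------------------------------------------------------------------------
# frame changes


def rotate_to_prolate(S_fib, Q):
    """Rotate fiber-frame tensor components to prolate components,
    S_prolate = Q S_fiber Q^T (vectorised)."""
    return np.einsum("...ij,...jk,...lk->...il", Q, S_fib, Q)
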