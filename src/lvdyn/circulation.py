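"""Lumped-parameter circulation coupled to the LV cavity.

Pulmonary bed (constant pressure P_PA) -> resistance R_PULM -> atrium
(compliance C_A, pressure P_A) -> mitral valve R_MV -> LV cavity (pressure p,
algebraic) -> aortic valve R_AOV -> proximal aortic node P_aov -> aortic
impedance R_AO -> aorta (compliance C_SYST, pressure P_AO) -> systemic bed
R_SYST -> venous pressure P_SV.

Both valves are smooth pressure-gated resistances switching between a closed
value R_cc and the open values along a logistic sigmoid of steepness beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CirculationParams", "CirculationState", "valve_resistances",
           "proximal_aortic_pressure", "circuit_rates"]


@dataclass(frozen=True)
class CirculationParams:
    """Circulation parameters (kPa, s, cm^3).

    The sigmoid steepness ``beta`` (1/kPa) and closed-valve resistance
    ``R_cc`` are model closures (no measured values exist); the defaults give
    sharp but smooth switching over ~0.1 kPa and a closed-valve leak below
    1 cm^3/s at physiological gradients.
    """

    R_PULM: float = 0.023
    R_SYST: float = 0.11
    R_AO: float = 0.001
    R_op_mv: float = 0.0008
    R_op_aov: float = 0.0005
    C_A: float = 20.0
    C_SYST: float = 10.0
    P_PA: float = 3.0
    P_SV: float = 6.0
    R_cc: float = 10.0
    beta: float = 50.0

    def __post_init__(self):
        for v in (self.R_PULM, self.R_SYST, self.R_AO, self.R_op_mv,
                  self.R_op_aov, self.C_A, self.C_SYST, self.R_cc, self.beta):
            if v <= 0:
                raise ValueError("resistances, compliances and beta must be > 0")
        if self.R_cc <= 10 * max(self.R_op_mv, self.R_op_aov):
            raise ValueError("R_cc must greatly exceed the open resistances")


@dataclass
class CirculationState:
    P_A: float
    P_AO: float
    p: float = 0.0
    P_aov: float = 0.0
    R_MV: float = 0.0
    R_AOV: float = 0.0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500.0, 500.0)))


def valve_resistances(P_A, p, P_aov, params: CirculationParams):
    """Mitral and aortic valve resistances.

    R_MV = R_cc - (R_cc - R_op_mv) / (1 + exp(-beta (P_A - p)))
    R_AOV = R_cc - (R_cc - R_op_aov) / (1 + exp(-beta (p - P_aov)))

    Smooth and monotone in the driving pressure difference, bounded in
    [R_op, R_cc].
    """
    R_MV = params.R_cc - (params.R_cc - params.R_op_mv) * _sigmoid(
        params.beta * (P_A - p))
    R_AOV = params.R_cc - (params.R_cc - params.R_op_aov) * _sigmoid(
        params.beta * (p - P_aov))
    return R_MV, R_AOV


def proximal_aortic_pressure(p, P_AO, R_AOV, params: CirculationParams):
    """P_aov = (p R_AO + P_AO R_AOV) / (R_AO + R_AOV): the resistive divider
    between the cavity and the aortic node."""
    return (p * params.R_AO + P_AO * R_AOV) / (params.R_AO + R_AOV)


def solve_proximal_node(p, P_AO, params: CirculationParams,
                        tol: float = 1e-13, max_iter: int = 60):
    """Solve the implicit proximal aortic node: R_AOV depends on P_aov
    through the valve sigmoid while P_aov depends on R_AOV through the
    divider.  Scalar Newton with bisection safeguard on

        h(P_aov) = (P_aov - P_AO) R_AOV(p, P_aov) + (P_aov - p) R_AO = 0

    which is monotone increasing; the root lies between p and P_AO.
    """
    lo, hi = min(p, P_AO) - 1e-9, max(p, P_AO) + 1e-9
    x = 0.5 * (lo + hi)
    bta, Rcc, Rop, Rao = params.beta, params.R_cc, params.R_op_aov, params.R_AO
    for _ in range(max_iter):
        s = _sigmoid(bta * (p - x))
        R = Rcc - (Rcc - Rop) * s
        hval = (x - P_AO) * R + (x - p) * Rao
        dR = (Rcc - Rop) * s * (1.0 - s) * bta  # dR/dP_aov
        dh = R + (x - P_AO) * dR + Rao
        if hval > 0:
            hi = x
        else:
            lo = x
        step = hval / dh if dh > 0 else 0.0
        x_new = x - step
        if not (lo <= x_new <= hi):
            x_new = 0.5 * (lo + hi)
        if abs(x_new - x) < tol * max(1.0, abs(x)):
            return x_new
        x = x_new
    return x


def circuit_rates(circ: CirculationState, dV_dt, params: CirculationParams):
    """Atrial and aortic pressure rates and the cavity flow-balance residual.

    dP_A/dt = [(P_PA - P_A)/R_PULM - (P_A - p)/R_MV] / C_A
    dP_AO/dt = [(P_aov - P_AO)/R_AO - (P_AO - P_SV)/R_SYST] / C_SYST
    residual = dV/dt - (P_A - p)/R_MV + (p - P_aov)/R_AOV
    """
    q_mv = (circ.P_A - circ.p) / circ.R_MV
    q_ao = (circ.p - circ.P_aov) / circ.R_AOV
    dP_A = ((params.P_PA - circ.P_A) / params.R_PULM - q_mv) / params.C_A
    dP_AO = ((circ.P_aov - circ.P_AO) / params.R_AO
             - (circ.P_AO - params.P_SV) / params.R_SYST) / params.C_SYST
    return dP_A, dP_AO, dV_dt - q_mv + q_ao
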