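"""Closed-form arrhythmia risk on the anisotropic cable lattice.

A dysfunctional cell together with the stretch of transversely uncoupled
cells to its right forms a potential microreentry circuit.  Writing
p_nu = 1 - (1 - nu)^2 for the probability that a cell has at least one
transverse coupling, the distance ell from a dysfunctional cell to the
first transversely coupled cell at or to its right is geometric, and the
probability that the circuit is too short to reenter (ell < tau/2) is

    P(ell < tau/2) = sum_{ell=0}^{tau/2-1} (1 - p_nu)^ell p_nu
                   = 1 - (1 - nu)^tau .

With delta*L^2 dysfunctional cells on average, the risk of at least one
fibrillation-inducing structure in the sheet is

    P_risk = 1 - [1 - (1 - nu)^tau]^(delta L^2),

and the point of steepest slope of P_risk defines the coupling threshold

    nu_star ~= 1 - (delta L^2)^(-1/tau)        (tau >> 1, delta L^2 tau >> 1)

below which fibrillation-prone structures proliferate.  All arithmetic is
carried out through log1p/expm1 so that exponents of order 10^3 and
larger do not underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .substrate import PhysicalParams, _check_prob

__all__ = [
    "RiskCurve",
    "p_transverse",
    "p_short_circuit",
    "p_risk",
    "p_risk_physical",
    "nu_star",
    "risk_curve",
]


def p_transverse(nu: float) -> float:
    """Probability that a cell has at least one transverse coupling."""
    _check_prob("nu", nu)
    return 1.0 - (1.0 - nu) ** 2


def p_short_circuit(nu: float, tau: int) -> float:
    """Probability that a dysfunctional cell's circuit is subcritical.

    Equals the geometric sum over ell < tau/2 and collapses to the closed
    form 1 - (1 - nu)^tau.  For even tau the sum has exactly tau/2 terms;
    for odd tau the closed form is used directly (the criticality cutoff
    ell >= tau/2 then falls on a half-integer; see docs/methods.md).
    """
    _check_prob("nu", nu)
    if int(tau) != tau or tau < 1:
        raise ValueError(f"tau must be an integer >= 1, got {tau!r}")
    if nu >= 1.0:
        return 1.0
    return -math.expm1(tau * math.log1p(-nu))


def p_risk(nu: float, tau: int, delta: float, L: int) -> float:
    """Probability of at least one fibrillation-inducing structure.

    P_risk = 1 - [1 - (1-nu)^tau]^(delta L^2).  Decreasing in nu and tau,
    increasing in delta and L.
    """
    _check_prob("nu", nu)
    _check_prob("delta", delta)
    if int(tau) != tau or tau < 1:
        raise ValueError(f"tau must be an integer >= 1, got {tau!r}")
    if int(L) != L or L < 1:
        raise ValueError(f"L must be an integer >= 1, got {L!r}")
    return _p_risk_real(nu, float(tau), delta * float(L) ** 2)


def _p_risk_real(nu: float, tau_exp: float, n_dysf: float) -> float:
    """P_risk with real-valued exponents (log-space throughout)."""
    if nu >= 1.0:
        return 0.0
    if nu <= 0.0:
        return 1.0 if n_dysf > 0 else 0.0
    q = tau_exp * math.log1p(-nu)          # log (1-nu)^tau
    if q >= 0:                              # tau_exp == 0
        return 1.0
    # log [1 - (1-nu)^tau]; -expm1(q) in (0, 1)
    log_safe = math.log1p(-math.exp(q)) if q > -700 else 0.0
    return -math.expm1(n_dysf * log_safe)


def p_risk_physical(phys: PhysicalParams, nu: float, delta: float) -> float:
    """P_risk expressed directly in tissue units.

    P_risk = 1 - [1 - (1-nu)^(theta_x tau' / (b dx))]^(delta L'^2 / (b^2 dx dy))

    where theta_x = dx/dt is the longitudinal conduction velocity.  With
    the default tissue values the exponents equal their dimensionless
    counterparts, tau = 50 and delta L^2 = 2000.
    """
    _check_prob("nu", nu)
    _check_prob("delta", delta)
    tau_exp = phys.theta_x * phys.tau_phys / (phys.b * phys.dx)
    n_dysf = delta * (phys.L_phys * 1e4) ** 2 / (phys.b**2 * phys.dx * phys.dy)
    if tau_exp <= 0:
        raise ValueError(f"refractory exponent must be positive, got {tau_exp!r}")
    if n_dysf < 0:
        raise ValueError(f"dysfunctional-cell exponent must be >= 0, got {n_dysf!r}")
    return _p_risk_real(nu, tau_exp, n_dysf)


def nu_star(delta: float, L: int, tau: int) -> float:
    """Coupling threshold: the point of steepest slope of P_risk.

    nu_star = 1 - (delta L^2)^(-1/tau), valid for tau >> 1 and
    delta L^2 tau >> 1.  Decreases with increasing refractory period.
    """
    _check_prob("delta", delta)
    if int(L) != L or L < 1:
        raise ValueError(f"L must be an integer >= 1, got {L!r}")
    if int(tau) != tau or tau < 1:
        raise ValueError(f"tau must be an integer >= 1, got {tau!r}")
    m = delta * float(L) ** 2
    if m <= 1.0:
        raise ValueError(f"delta * L^2 must exceed 1 for a threshold to exist, got {m!r}")
    return -math.expm1(-math.log(m) / tau)


@dataclass(frozen=True)
class RiskCurve:
    """P_risk evaluated on a grid of nu (the analytic phase-diagram line)."""

    nu_values: np.ndarray
    p_risk_values: np.ndarray
    params: tuple  # (tau, delta, L)


def risk_curve(nu_grid, tau: int, delta: float, L: int) -> RiskCurve:
    """Evaluate P_risk elementwise over ``nu_grid`` (monotone non-increasing)."""
    nu_values = np.asarray(list(nu_grid), dtype=float)
    values = np.array([p_risk(nu, tau, delta, L) for nu in nu_values])
    return RiskCurve(nu_values=nu_values, p_risk_values=values, params=(tau, delta, L))
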