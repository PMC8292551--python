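"""Closed-form reference solutions used to cross-check the ODE solver.

These are independent of the numerical integration path: the malignant-cell
survival S_M solves an autonomous constant-coefficient Riccati equation

    dS/dtau = beta_M - (alpha_M + beta_M + rho) S + alpha_M S^2,  S(0) = 1,

whose solution is expressed through the roots of
alpha_M x^2 - (alpha_M + beta_M + rho) x + beta_M = 0.
"""

from __future__ import annotations

import numpy as np

from .params import BiologicalParams

__all__ = ["riccati_sm", "riccati_roots"]


def riccati_roots(alpha_m: float, beta_m: float, rho: float) -> tuple[float, float]:
    """Roots (r1 <= r2) of alpha_M x^2 - (alpha_M+beta_M+rho) x + beta_M."""
    b = alpha_m + beta_m + rho
    disc = b * b - 4.0 * alpha_m * beta_m
    sq = np.sqrt(disc)
    r1 = (b - sq) / (2.0 * alpha_m)
    r2 = (b + sq) / (2.0 * alpha_m)
    return r1, r2


def riccati_sm(params: BiologicalParams, tau) -> np.ndarray:
    """Closed-form S_M(tau) for a single malignant cell.

    Handles the linear degenerate case alpha_M == 0 analytically.
    """
    tau = np.asarray(tau, dtype=float)
    a, b, rho = params.alphaM, params.betaM, params.rho
    if rho == 0.0:
        return np.ones_like(tau)
    if a == 0.0:
        # dS/dtau = b - (b + rho) S, S(0) = 1
        k = b + rho
        s_inf = b / k if k > 0 else 1.0
        return s_inf + (1.0 - s_inf) * np.exp(-k * tau)
    r1, r2 = riccati_roots(a, b, rho)
    # u = (S - r1)/(S - r2) evolves as u0 * exp(a (r1 - r2) tau)
    u0 = (1.0 - r1) / (1.0 - r2)
    u = u0 * np.exp(a * (r1 - r2) * tau)
    return (r1 - r2 * u) / (1.0 - u)
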