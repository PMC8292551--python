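"""Backward survival ODEs and the population age-specific OAC hazard.

The post-onset process is described by "no detection by time tau" survival
probabilities for a single cell of each type: malignant (S_M), premalignant
(S_P), one-hit (S_1) and BE stem cell (S_0).  With parent-persists spawning
semantics the coupled backward system is

    dS_M/dtau = beta_M - (alpha_M + beta_M + rho) S_M + alpha_M S_M^2
    dS_P/dtau = beta_P - (alpha_P + beta_P + mu2) S_P + alpha_P S_P^2
                + mu2 S_P S_M
    dS_1/dtau = mu1 S_1 (S_P - 1)
    dS_0/dtau = mu0 S_0 (S_1 - 1)

with all initial values 1.  A whole BE segment of N(L) stem cells survives
as S_0^N(L); marginalising over the Beta length law gives S_BE(tau).  Mixing
S_BE over the BE onset age distribution yields the population hazard
h_OAC(t), the population survival S_pop(t), and the prevalence of
cancer-free BE among alive cancer-free persons, p_be_cf(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConfigError, InputError, NumericalError
from .params import BeSegmentModel, BiologicalParams

__all__ = [
    "SurvivalSolution",
    "BeSurvival",
    "HazardCurve",
    "solve_backward_system",
    "be_survival",
    "population_hazard",
    "incidence_per_100k",
]

# numerical guards
_S_TOL = 1e-6          # tolerance on S leaving [0, 1]
_SPOP_FLOOR = 1e-12    # population survival underflow floor


def _check_grid(grid: np.ndarray, name: str) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise InputError(f"{name} must be a 1-d array with at least 2 points")
    if grid[0] != 0.0:
        raise InputError(f"{name} must start at 0, got {grid[0]!r}")
    if not np.all(np.diff(grid) > 0):
        raise InputError(f"{name} must be strictly increasing")
    if np.any(grid < 0) or not np.all(np.isfinite(grid)):
        raise InputError(f"{name} must be finite and nonnegative")
    return grid


@dataclass(frozen=True)
class SurvivalSolution:
    """Single-cell no-detection survival curves on a tau grid.

    tau is time since BE onset in years.  ``dS0`` is the analytic
    derivative of ``S_0`` evaluated on the grid.
    """

    params: BiologicalParams
    tau_grid: np.ndarray
    S_M: np.ndarray
    S_P: np.ndarray
    S_1: np.ndarray
    S_0: np.ndarray
    dS0: np.ndarray


@dataclass(frozen=True)
class BeSurvival:
    """Whole-segment survival S_BE(tau) and its derivative on a tau grid."""

    tau_grid: np.ndarray
    s: np.ndarray
    ds: np.ndarray

    def __call__(self, tau) -> np.ndarray:
        return np.interp(tau, self.tau_grid, self.s)

    def deriv(self, tau) -> np.ndarray:
        return np.interp(tau, self.tau_grid, self.ds)


@dataclass(frozen=True)
class HazardCurve:
    """Population age-specific hazard of first OAC detection.

    ``h_oac`` is per person-year among persons alive and cancer-free;
    ``s_pop`` the probability of no detected OAC by age; ``p_be_cf`` the
    prevalence of cancer-free BE among alive cancer-free persons.
    """

    age_grid: np.ndarray
    h_oac: np.ndarray
    s_pop: np.ndarray
    p_be_cf: np.ndarray
    sex: str = ""
    cohort: Optional[int] = None
    subgroup: str = "population"

    @property
    def incidence_per_100k(self) -> np.ndarray:
        return 1e5 * self.h_oac

    def hazard_at(self, age) -> np.ndarray:
        return np.interp(age, self.age_grid, self.h_oac)

    def prevalence_at(self, age) -> np.ndarray:
        return np.interp(age, self.age_grid, self.p_be_cf)

    def survival_at(self, age) -> np.ndarray:
        return np.interp(age, self.age_grid, self.s_pop)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "age": self.age_grid,
                "hazard": self.h_oac,
                "survival": self.s_pop,
                "be_prevalence_cancer_free": self.p_be_cf,
                "incidence_per_100k": self.incidence_per_100k,
                "sex": self.sex,
                "cohort": self.cohort if self.cohort is not None else "",
                "subgroup": self.subgroup,
            }
        )


def solve_backward_system(
    params: BiologicalParams,
    tau_grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SurvivalSolution:
    """Solve the coupled backward survival system on ``tau_grid``.

    Uses adaptive Runge–Kutta; raises :class:`NumericalError` naming the
    offending component if any survival probability leaves [0, 1] beyond
    the solver tolerance.
    """
    tau_grid = _check_grid(tau_grid, "tau_grid")
    p = params

    def rhs(_t, y):
        s_m, s_p, s_1, s_0 = y
        return (
            p.betaM - (p.alphaM + p.betaM + p.rho) * s_m + p.alphaM * s_m * s_m,
            p.betaP
            - (p.alphaP + p.betaP + p.mu2) * s_p
            + p.alphaP * s_p * s_p
            + p.mu2 * s_p * s_m,
            p.mu1 * s_1 * (s_p - 1.0),
            p.mu0 * s_0 * (s_1 - 1.0),
        )

    sol = solve_ivp(
        rhs,
        (0.0, float(tau_grid[-1])),
        [1.0, 1.0, 1.0, 1.0],
        t_eval=tau_grid,
        rtol=rtol,
        atol=atol,
        method="LSODA",
    )
    if not sol.success:
        raise NumericalError(f"backward survival ODE solver failed: {sol.message}")

    names = ("S_M", "S_P", "S_1", "S_0")
    curves = {}
    for i, name in enumerate(names):
        s = sol.y[i]
        if np.any(s < -_S_TOL) or np.any(s > 1.0 + _S_TOL):
            raise NumericalError(
                f"survival component {name} left [0, 1] "
                f"(min {s.min():.3e}, max {s.max():.3e})"
            )
        curves[name] = np.clip(s, 0.0, 1.0)

    d_s0 = p.mu0 * curves["S_0"] * (curves["S_1"] - 1.0)
    return SurvivalSolution(
        params=params,
        tau_grid=tau_grid,
        S_M=curves["S_M"],
        S_P=curves["S_P"],
        S_1=curves["S_1"],
        S_0=curves["S_0"],
        dS0=d_s0,
    )


def be_survival(solution: SurvivalSolution, segment: BeSegmentModel) -> BeSurvival:
    """Marginalise single-stem-cell survival over the segment length law.

    S_BE(tau) = E_L[S_0(tau)^N(L)] with N(L) = cells_per_cm * L, computed
    by fixed-node Gauss–Legendre quadrature over the Beta length
    distribution; the derivative is the analytic
    E_L[N(L) S_0^(N(L)-1) dS0].
    """
    lengths, weights = segment.quadrature()
    n_cells = segment.stem_cells(lengths)  # (q,)
    s0 = solution.S_0[:, None]  # (t, 1)
    ds0 = solution.dS0[:, None]

    # S_0^N; S_0 > 0 in practice, guard the log for S_0 == 0 exactly
    with np.errstate(divide="ignore"):
        log_s0 = np.where(s0 > 0.0, np.log(np.maximum(s0, 1e-300)), -np.inf)
    powered = np.exp(n_cells[None, :] * log_s0)  # (t, q)
    s_be = powered @ weights
    ds_be = (n_cells[None, :] * np.where(s0 > 0, powered / np.maximum(s0, 1e-300), 0.0) * ds0) @ weights

    s_be = np.clip(s_be, 0.0, 1.0)
    return BeSurvival(tau_grid=solution.tau_grid, s=s_be, ds=ds_be)


def _conv_trapz(f: np.ndarray, g: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoid-rule convolution integral I_i = int_0^{t_i} f(s) g(t_i - s) ds
    on a uniform grid with spacing dt."""
    n = f.size
    full = np.convolve(f, g)[:n]
    corr = 0.5 * (f[0] * g + f * g[0])
    return dt * (full - corr)


def population_hazard(
    be_surv: BeSurvival,
    onset,
    age_grid,
    subgroup: str = "population",
    sex: Optional[str] = None,
    cohort: Optional[int] = None,
    s_pop_floor: float = _SPOP_FLOOR,
) -> HazardCurve:
    """Mix the post-onset survival over BE onset age to get h_OAC(t).

    Single-conversion BE onset with hazard nu(t) and cumulative
    Lambda(t):

        S_pop(t)  = e^{-Lambda(t)} + int_0^t nu(s) e^{-Lambda(s)} S_BE(t-s) ds
        h_OAC(t)  = int_0^t nu(s) e^{-Lambda(s)} (-S_BE'(t-s)) ds / S_pop(t)
        p_be_cf(t)= int_0^t nu(s) e^{-Lambda(s)} S_BE(t-s) ds / S_pop(t)

    ``onset`` is a :class:`~msceoac.onset.BeOnsetModel`; outer integrals
    use the trapezoid rule on the uniform ``age_grid``, which must share
    its spacing with ``be_surv.tau_grid``.
    """
    age_grid = _check_grid(age_grid, "age_grid")
    steps = np.diff(age_grid)
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=0, atol=1e-9 * dt):
        raise InputError("age_grid must be uniformly spaced")
    tau = be_surv.tau_grid
    if tau.size < age_grid.size or not np.allclose(
        tau[: age_grid.size], age_grid, rtol=0, atol=1e-9 * dt
    ):
        raise InputError(
            "be_surv.tau_grid must cover age_grid with identical spacing"
        )

    nu = np.asarray(onset.onset_rate(age_grid, subgroup=subgroup), dtype=float)
    if nu.shape != age_grid.shape:
        nu = np.full_like(age_grid, float(nu))
    lam = np.concatenate(([0.0], np.cumsum(0.5 * (nu[1:] + nu[:-1]) * dt)))
    f = nu * np.exp(-lam)

    s_be = be_surv.s[: age_grid.size]
    ds_be = be_surv.ds[: age_grid.size]

    with_be = _conv_trapz(f, s_be, dt)
    num_h = _conv_trapz(f, -ds_be, dt)
    s_pop = np.exp(-lam) + with_be
    if np.any(s_pop < s_pop_floor):
        raise NumericalError(
            f"population survival underflowed below floor {s_pop_floor:g}"
        )
    h = np.maximum(num_h, 0.0) / s_pop
    p_be = np.clip(with_be / s_pop, 0.0, 1.0)
    return HazardCurve(
        age_grid=age_grid,
        h_oac=h,
        s_pop=np.clip(s_pop, 0.0, 1.0),
        p_be_cf=p_be,
        sex=sex if sex is not None else getattr(onset, "sex", ""),
        cohort=cohort if cohort is not None else getattr(onset, "cohort", None),
        subgroup=subgroup,
    )


def incidence_per_100k(curve: HazardCurve) -> np.ndarray:
    """Hazard expressed as cases per 100,000 person-years."""
    return 1e5 * np.asarray(curve.h_oac, dtype=float)
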