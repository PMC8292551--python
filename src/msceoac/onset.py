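"""GERD prevalence and the GERD-stratified Barrett's-oesophagus onset model.

BE conversion is a single event with age-dependent hazard nu(t).  In the
general population the rate is the prevalence-weighted mixture of the
GERD and non-GERD subgroup rates,

    nu_pop(t) = nu0 * m_cohort * [1 + (RR - 1) * p_GERD(t)],

where RR is the relative risk of conversion for GERD vs non-GERD and
p_GERD(t) the age-specific GERD prevalence.  Unconditional BE prevalence
(ignoring cancer) is 1 - exp(-Lambda(t)) with Lambda the cumulative
hazard; the cancer-free conditional prevalence comes from
:func:`msceoac.hazard.population_hazard`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "GerdModel",
    "BeOnsetModel",
    "onset_rate",
    "cumulative_onset",
    "be_prevalence",
    "gerd_subgroup_prevalence_curve",
    "SUBGROUPS",
]

SUBGROUPS = ("population", "gerd", "non_gerd")


@dataclass(frozen=True)
class GerdModel:
    """Age-specific GERD prevalence and the BE-conversion relative risk.

    Prevalence is either logistic, p(t) = p_max / (1 + exp(-k (t - t0))),
    or tabulated on integer ages (linearly interpolated in between).
    """

    rr: float = 5.0
    p_max: Optional[float] = None
    k: Optional[float] = None
    t0: Optional[float] = None
    table_ages: Optional[np.ndarray] = None
    table_prev: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.rr < 1.0 or not np.isfinite(self.rr):
            raise ConfigError(f"GerdModel.rr must be >= 1, got {self.rr!r}")
        if self.table_ages is None:
            if self.p_max is None or self.k is None or self.t0 is None:
                raise ConfigError(
                    "GerdModel needs either (p_max, k, t0) or a prevalence table"
                )
            if not 0.0 <= self.p_max <= 1.0:
                raise ConfigError(f"GerdModel.p_max must be in [0,1], got {self.p_max!r}")
            if self.k <= 0:
                raise ConfigError(f"GerdModel.k must be > 0, got {self.k!r}")
        else:
            prev = np.asarray(self.table_prev, dtype=float)
            if np.any(prev < 0) or np.any(prev > 1):
                raise ConfigError("tabulated GERD prevalence must lie in [0,1]")

    @classmethod
    def from_logistic(cls, p_max: float, k: float, t0: float, rr: float = 5.0) -> "GerdModel":
        return cls(rr=rr, p_max=p_max, k=k, t0=t0)

    @classmethod
    def from_table(cls, ages, prevalence, rr: float = 5.0) -> "GerdModel":
        ages = np.asarray(ages, dtype=float)
        prev = np.asarray(prevalence, dtype=float)
        if ages.shape != prev.shape or ages.size == 0:
            raise ConfigError("GERD table ages and prevalence must match and be non-empty")
        order = np.argsort(ages)
        return cls(rr=rr, table_ages=ages[order], table_prev=prev[order])

    def prevalence(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if self.table_ages is not None:
            return np.interp(age, self.table_ages, self.table_prev)
        return self.p_max / (1.0 + np.exp(-self.k * (age - self.t0)))


@dataclass(frozen=True)
class BeOnsetModel:
    """Baseline BE conversion rate nu0 with cohort and GERD structure.

    ``cohort`` selects a multiplier from ``cohort_multipliers`` (decade
    start year -> positive scale on nu0); ``None`` means multiplier 1.
    """

    nu0: float
    gerd: GerdModel
    cohort_multipliers: Mapping[int, float] = field(default_factory=dict)
    sex: str = ""
    cohort: Optional[int] = None
    grid_step: float = 0.1

    def __post_init__(self) -> None:
        if self.nu0 < 0 or not np.isfinite(self.nu0):
            raise ConfigError(f"nu0 must be >= 0 and finite, got {self.nu0!r}")
        for c, m in self.cohort_multipliers.items():
            if m <= 0:
                raise ConfigError(f"cohort multiplier for {c} must be > 0, got {m!r}")
        if self.cohort is not None and self.cohort_multipliers and (
            self.cohort not in self.cohort_multipliers
        ):
            raise ConfigError(
                f"cohort {self.cohort} has no multiplier; known cohorts: "
                f"{sorted(self.cohort_multipliers)}"
            )

    @property
    def multiplier(self) -> float:
        if self.cohort is None or not self.cohort_multipliers:
            return 1.0
        return float(self.cohort_multipliers[self.cohort])

    def for_cohort(self, cohort: Optional[int]) -> "BeOnsetModel":
        return replace(self, cohort=cohort)

    def with_rr(self, rr: float) -> "BeOnsetModel":
        return replace(self, gerd=replace(self.gerd, rr=rr))

    # -- operations -------------------------------------------------

    def onset_rate(self, age, subgroup: str = "population") -> np.ndarray:
        return onset_rate(self, age, subgroup)

    def cumulative_onset(self, age, subgroup: str = "population") -> np.ndarray:
        return cumulative_onset(self, age, subgroup)

    def be_prevalence(self, age, subgroup: str = "population") -> np.ndarray:
        return be_prevalence(self, age, subgroup)


def onset_rate(model: BeOnsetModel, age, subgroup: str = "population") -> np.ndarray:
    """BE conversion hazard nu(t) per year for a subgroup.

    population: nu0*m*[1 + (RR-1) p_GERD(t)]; gerd: nu0*m*RR;
    non_gerd: nu0*m.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise InputError("age must be >= 0")
    base = model.nu0 * model.multiplier
    rr = model.gerd.rr
    if subgroup == "population":
        return base * (1.0 + (rr - 1.0) * model.gerd.prevalence(age))
    if subgroup == "gerd":
        return np.full_like(age, base * rr)
    if subgroup == "non_gerd":
        return np.full_like(age, base)
    raise InputError(f"unknown subgroup {subgroup!r}; expected one of {SUBGROUPS}")


def cumulative_onset(model: BeOnsetModel, age, subgroup: str = "population") -> np.ndarray:
    """Lambda(age) = int_0^age nu(s) ds by trapezoid on the model grid."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise InputError("age must be >= 0")
    a_max = float(np.max(age)) if age.size else 0.0
    n = max(2, int(np.ceil(a_max / model.grid_step)) + 1)
    grid = np.linspace(0.0, max(a_max, model.grid_step), n)
    nu = onset_rate(model, grid, subgroup)
    lam_grid = np.concatenate(
        ([0.0], np.cumsum(0.5 * (nu[1:] + nu[:-1]) * np.diff(grid)))
    )
    return np.interp(age, grid, lam_grid)


def be_prevalence(model: BeOnsetModel, age, subgroup: str = "population") -> np.ndarray:
    """Unconditional (cancer-ignored) BE prevalence 1 - exp(-Lambda)."""
    return 1.0 - np.exp(-cumulative_onset(model, age, subgroup))


def gerd_subgroup_prevalence_curve(
    model: BeOnsetModel,
    age_grid,
    rr_values,
    be_surv,
) -> dict[float, np.ndarray]:
    """Cancer-free BE prevalence curves for the GERD subgroup per RR.

    For each relative risk the GERD subgroup converts at rr * nu0 * m;
    the curve is p_be_cf from the full population-hazard mixture for that
    subgroup, so it accounts for depletion by cancer detection.
    """
    rr_values = list(rr_values)
    if not rr_values:
        raise InputError("rr_values must be non-empty")
    if any(r < 1.0 for r in rr_values):
        raise InputError("all rr values must be >= 1")
    from .hazard import population_hazard

    curves: dict[float, np.ndarray] = {}
    for rr in rr_values:
        m = model.with_rr(rr)
        curve = population_hazard(be_surv, m, age_grid, subgroup="gerd")
        curves[float(rr)] = curve.p_be_cf
    return curves
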