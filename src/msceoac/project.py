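"""Population burden projection from hazards and census person-years.

Combines stratified hazard curves with a census-style person-year table
to produce expected annual OAC case counts (with percentile intervals
propagated from parameter draws), prevalent cancer-free BE carrier
counts, BE-to-OAC progression rates, attributable fractions and scenario
sweeps over the GERD relative risk and GERD prevalence scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import Config
from .errors import InputError
from .hazard import HazardCurve
from .model import HazardEvaluator

__all__ = [
    "CasePrediction",
    "expected_cases",
    "prediction_interval",
    "be_carrier_count",
    "progression_rate",
    "attributable_fraction",
    "sweep_scenarios",
]

logger = logging.getLogger(__name__)

_PREVALENCE_FLOOR = 1e-8


@dataclass
class CasePrediction:
    """Expected case counts for one calendar year."""

    year: int
    by_stratum: pd.DataFrame
    total: float
    interval: Optional[tuple[float, float]] = None
    interval_level: Optional[float] = None
    be_carriers: Optional[float] = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        strata_sum = float(self.by_stratum["expected_cases"].sum())
        if abs(strata_sum - self.total) > 1e-9 * max(1.0, abs(self.total)):
            raise InputError(
                f"stratum sum {strata_sum!r} does not match total {self.total!r}"
            )
        if self.interval is not None:
            lo, hi = self.interval
            if not lo <= self.total <= hi:
                logger.warning(
                    "point estimate %.1f outside interval (%.1f, %.1f)",
                    self.total, lo, hi,
                )

    def to_json_dict(self) -> dict:
        return {
            "year": self.year,
            "total_expected_cases": self.total,
            "interval": list(self.interval) if self.interval else None,
            "interval_level": self.interval_level,
            "be_carriers": self.be_carriers,
            "settings": self.settings,
        }


def _cohort_bin(year: int, age: float) -> int:
    return int(np.floor((year - age) / 10.0) * 10)


class _CurveLookup:
    """Resolves (sex, cohort bin) to a hazard curve with nearest-cohort
    clamping for cohorts outside the fitted range (logged once each)."""

    def __init__(self, hazards, overrides: Optional[Mapping[str, float]] = None):
        self._overrides = dict(overrides) if overrides else None
        if isinstance(hazards, HazardEvaluator):
            self._evaluator = hazards
            self._known = sorted(hazards.cfg.cohort_multipliers)
            self._dict = None
        elif isinstance(hazards, Mapping):
            if self._overrides:
                raise InputError("parameter overrides need a HazardEvaluator")
            self._evaluator = None
            self._dict = dict(hazards)
            self._known = sorted({c for (_s, c) in self._dict})
        else:
            raise InputError(
                "hazards must be a HazardEvaluator or a mapping (sex, cohort) -> HazardCurve"
            )
        if not self._known:
            raise InputError("no cohorts available in hazards")
        self._warned: set[int] = set()

    def clamp(self, cohort: int) -> int:
        if cohort in self._known:
            return cohort
        nearest = min(self._known, key=lambda c: abs(c - cohort))
        if cohort not in self._warned:
            logger.debug("cohort %d outside fitted range; using %d", cohort, nearest)
            self._warned.add(cohort)
        return nearest

    def get(self, sex: str, cohort: int) -> HazardCurve:
        cohort = self.clamp(cohort)
        if self._evaluator is not None:
            return self._evaluator.curve(sex, cohort, overrides=self._overrides)
        try:
            return self._dict[(sex, cohort)]
        except KeyError:
            raise InputError(f"no hazard curve for stratum ({sex!r}, {cohort})")


def _census_slice(census: pd.DataFrame, year: int, age_range) -> pd.DataFrame:
    sub = census[census["year"] == year]
    if sub.empty:
        raise InputError(f"census table has no rows for year {year}")
    lo, hi = age_range
    sub = sub[(sub["age"] >= lo) & (sub["age"] <= hi)]
    if sub.empty:
        raise InputError(f"census table has no ages in range {age_range}")
    return sub


def _stratum_weights(census: pd.DataFrame, year: int, age_range):
    """Group census person-years by (sex, cohort bin) into age/PY arrays."""
    sub = _census_slice(census, year, age_range)
    grouped: dict[tuple[str, int], list[tuple[float, float]]] = {}
    agg = sub.groupby(["sex", "age"], sort=True)["person_years"].sum()
    for (sex, age), py in agg.items():
        grouped.setdefault((sex, _cohort_bin(year, age)), []).append((float(age), float(py)))
    return [
        (sex, cohort, np.array([a for a, _ in rows]), np.array([p for _, p in rows]))
        for (sex, cohort), rows in grouped.items()
    ]


def _total_for_overrides(lookup: "_CurveLookup", weights) -> float:
    total = 0.0
    for sex, cohort, ages, py in weights:
        curve = lookup.get(sex, cohort)
        total += float(py @ curve.hazard_at(ages + 0.5))
    return total


def expected_cases(
    hazards,
    census: pd.DataFrame,
    year: int,
    age_range: tuple[int, int] = (40, 90),
    overrides: Optional[Mapping[str, float]] = None,
) -> CasePrediction:
    """Expected OAC case count: sum of person-years times hazard.

    ``cases = sum over (sex, age) of PY(year, sex, age) * h_OAC(age; sex,
    cohort = year - age)`` with the cohort mapped to its 10-year bin.
    ``hazards`` is a HazardEvaluator or a mapping (sex, cohort) ->
    HazardCurve.
    """
    lookup = _CurveLookup(hazards, overrides)
    sub = _census_slice(census, year, age_range)
    rows = []
    for (sex, age), group in sub.groupby(["sex", "age"], sort=True):
        py = float(group["person_years"].sum())
        cohort = _cohort_bin(year, age)
        curve = lookup.get(sex, cohort)
        if age + 0.5 > curve.age_grid[-1]:
            raise InputError(
                f"age {age} outside hazard grid (max {curve.age_grid[-1]})"
            )
        h = float(curve.hazard_at(age + 0.5))
        rows.append(
            {
                "year": year,
                "sex": sex,
                "age": age,
                "cohort": lookup.clamp(cohort),
                "person_years": py,
                "hazard": h,
                "expected_cases": py * h,
            }
        )
    by_stratum = pd.DataFrame(rows)
    total = float(by_stratum["expected_cases"].sum())
    return CasePrediction(
        year=int(year),
        by_stratum=by_stratum,
        total=total,
        settings={"age_range": list(age_range), "overrides": dict(overrides or {})},
    )


def prediction_interval(
    evaluator: HazardEvaluator,
    census: pd.DataFrame,
    year: int,
    draws: pd.DataFrame,
    age_range: tuple[int, int] = (40, 90),
    level: float = 0.95,
    bounds: Optional[Mapping[str, tuple[float, float]]] = None,
) -> tuple[float, float]:
    """Percentile interval for the expected case count over parameter draws.

    Recomputes :func:`expected_cases` for every draw; draws violating the
    given parameter bounds are skipped (counted; more than 50% skipped is
    an error).  Deterministic given the draw matrix.
    """
    if len(draws) < 100:
        raise InputError("need at least 100 parameter draws")
    names = list(draws.columns)
    weights = _stratum_weights(census, year, age_range)
    totals = []
    n_skipped = 0
    for row in draws.itertuples(index=False):
        values = dict(zip(names, (float(v) for v in row)))
        if bounds is not None and any(
            not (bounds[n][0] <= values[n] <= bounds[n][1])
            for n in names
            if n in bounds
        ):
            n_skipped += 1
            continue
        totals.append(_total_for_overrides(_CurveLookup(evaluator, values), weights))
    if n_skipped:
        logger.info("skipped %d draws violating bounds", n_skipped)
    if n_skipped > 0.5 * len(draws):
        raise InputError(f"{n_skipped}/{len(draws)} draws violated parameter bounds")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(totals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def be_carrier_count(
    hazards,
    census: pd.DataFrame,
    year: int,
    age_range: tuple[int, int] = (40, 90),
    overrides: Optional[Mapping[str, float]] = None,
) -> tuple[float, float]:
    """Prevalent cancer-free BE carriers and the prevalence fraction.

    Returns ``(count, fraction)`` with count = sum PY * p_be_cf and
    fraction = count / total person-years in the age range.
    """
    lookup = _CurveLookup(hazards, overrides)
    sub = _census_slice(census, year, age_range)
    total_py = 0.0
    carriers = 0.0
    for (sex, age), group in sub.groupby(["sex", "age"], sort=True):
        py = float(group["person_years"].sum())
        curve = lookup.get(sex, _cohort_bin(year, age))
        carriers += py * float(curve.prevalence_at(age + 0.5))
        total_py += py
    return carriers, carriers / total_py


def progression_rate(
    curve: HazardCurve, age: float, floor: float = _PREVALENCE_FLOOR
) -> float:
    """Annual OAC incidence among prevalent cancer-free BE carriers.

    The model attributes all cases to BE, so the rate is
    h_OAC(age) / p_be_cf(age).
    """
    p = float(curve.prevalence_at(age))
    h = float(curve.hazard_at(age))
    if p <= floor:
        if h == 0.0:
            return 0.0
        raise InputError(
            f"BE prevalence {p:g} at age {age} below floor {floor:g}; "
            "progression rate undefined"
        )
    return h / p


def attributable_fraction(predicted_cases: float, observed_cases: float) -> dict:
    """Share of observed cases accounted for by the BE pathway, capped at 1.

    Returns ``{'fraction', 'unexplained', 'excess'}``; when the model
    over-predicts, fraction is 1 and the surplus is reported as
    ``excess``.
    """
    if observed_cases <= 0:
        raise InputError("observed_cases must be > 0")
    if predicted_cases < 0:
        raise InputError("predicted_cases must be >= 0")
    ratio = predicted_cases / observed_cases
    fraction = min(1.0, ratio)
    return {
        "fraction": fraction,
        "unexplained": 1.0 - fraction,
        "excess": max(0.0, ratio - 1.0),
    }


def sweep_scenarios(
    cfg: Config,
    sweep: Mapping[str, Sequence[float]],
    census: pd.DataFrame,
    year: int,
    age_range: Optional[tuple[int, int]] = None,
    progression_age: float = 60.0,
    prevalence_age: float = 50.0,
) -> pd.DataFrame:
    """One output row per scenario on a grid of RR and GERD-prevalence scalings.

    ``sweep`` may contain ``rr`` (GERD relative-risk values) and/or
    ``gerd_scale`` (multipliers on the GERD prevalence ceiling p_max).
    Each row reports expected cases, BE carrier count and fraction, the
    GERD-subgroup BE prevalence at ``prevalence_age``, and the
    BE-to-OAC progression rate at ``progression_age`` for the reference
    (latest) cohort, per sex where sex-specific.
    """
    valid = {"rr", "gerd_scale"}
    unknown = set(sweep) - valid
    if unknown:
        raise InputError(f"unknown sweep parameter(s) {sorted(unknown)}")
    rr_values = list(sweep.get("rr", [cfg.gerd().rr]))
    scale_values = list(sweep.get("gerd_scale", [1.0]))
    if not rr_values or not scale_values:
        raise InputError("sweep grids must be non-empty")
    if age_range is None:
        age_range = cfg.age_range
    ref_cohort = max(cfg.cohort_multipliers) if cfg.cohort_multipliers else None

    rows = []
    for rr in rr_values:
        for scale in scale_values:
            patch: dict = {"gerd": {"rr": float(rr)}}
            if scale != 1.0:
                curve_cfg = cfg.raw["gerd"]["curve"]
                if curve_cfg is None:
                    raise InputError(
                        f"scenario gerd_scale={scale}: no logistic curve to scale"
                    )
                p_max = float(curve_cfg["p_max"]) * float(scale)
                if not 0.0 <= p_max <= 1.0:
                    raise InputError(
                        f"scenario gerd_scale={scale}: scaled p_max {p_max:g} outside [0,1]"
                    )
                patch["gerd"]["curve"] = {"p_max": p_max}
            scen_cfg = cfg.updated(patch)
            ev = HazardEvaluator(scen_cfg)
            pred = expected_cases(ev, census, year, age_range)
            carriers, fraction = be_carrier_count(ev, census, year, age_range)
            row = {
                "rr": float(rr),
                "gerd_scale": float(scale),
                "expected_cases": pred.total,
                "be_carriers": carriers,
                "be_fraction": fraction,
            }
            for sex in scen_cfg.sexes:
                pop = ev.curve(sex, ref_cohort)
                gerd = ev.curve(sex, ref_cohort, subgroup="gerd")
                row[f"progression_{sex}"] = progression_rate(pop, progression_age)
                row[f"gerd_be_prevalence_{sex}"] = float(
                    gerd.prevalence_at(prevalence_age)
                )
            rows.append(row)
    return pd.DataFrame(rows)
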