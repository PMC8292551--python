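"""Synthetic study-shaped inputs generated from known ground truth.

Every input the pipeline consumes — registry-style incidence tables,
census-style person-year tables, GERD prevalence curves, and screening-
yield cohorts — can be generated here from a configuration whose
parameters are known, so that calibration, projection and model selection
are testable end to end without external data.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import Config
from .errors import InputError
from .model import HazardEvaluator

__all__ = [
    "make_gerd_curve",
    "make_census_table",
    "synth_incidence_table",
    "make_screening_cohort",
    "default_age_bins",
]


def default_age_bins() -> np.ndarray:
    """Registry-like 5-year age bins covering 40-89."""
    return np.arange(40.0, 95.0, 5.0)


def make_gerd_curve(
    p_max: float,
    k: float,
    t0: float,
    sexes: Sequence[str] = ("M", "F"),
) -> pd.DataFrame:
    """Logistic GERD prevalence tabulated on integer ages 0-100 per sex."""
    if not 0.0 <= p_max <= 1.0:
        raise InputError(f"p_max must be in [0,1], got {p_max!r}")
    if k <= 0:
        raise InputError(f"k must be > 0, got {k!r}")
    ages = np.arange(0, 101)
    prev = p_max / (1.0 + np.exp(-k * (ages - t0)))
    frames = [
        pd.DataFrame({"sex": sex, "age": ages, "prevalence": prev}) for sex in sexes
    ]
    return pd.concat(frames, ignore_index=True)


def make_census_table(
    year: int,
    total_py: float,
    pyramid: Optional[Mapping] = None,
    sexes: Sequence[str] = ("M", "F"),
    sex_split: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Person-years by (year, sex, single age 0-100) following an age pyramid.

    The default pyramid is flat to ``plateau_age`` (60) then declines
    linearly to zero at ``zero_age`` (100).  Rows sum to ``total_py``
    within 1e-6 relative.
    """
    if total_py <= 0:
        raise InputError("total_py must be > 0")
    pyramid = dict(pyramid or {})
    plateau = float(pyramid.pop("plateau_age", 60.0))
    zero_age = float(pyramid.pop("zero_age", 100.0))
    if pyramid:
        raise InputError(f"unknown pyramid key(s) {sorted(pyramid)}")
    if not 0 < plateau < zero_age:
        raise InputError("pyramid needs 0 < plateau_age < zero_age")
    ages = np.arange(0, 101)
    weights = np.where(
        ages <= plateau,
        1.0,
        np.clip((zero_age - ages) / (zero_age - plateau), 0.0, 1.0),
    )
    weights = weights / weights.sum()
    if sex_split is None:
        sex_split = {sex: 1.0 / len(sexes) for sex in sexes}
    if abs(sum(sex_split.values()) - 1.0) > 1e-9:
        raise InputError("sex_split fractions must sum to 1")
    frames = []
    for sex in sexes:
        frames.append(
            pd.DataFrame(
                {
                    "year": int(year),
                    "sex": sex,
                    "age": ages,
                    "person_years": total_py * sex_split[sex] * weights,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def synth_incidence_table(
    cfg: Config,
    py_per_stratum: float,
    seed: int,
    sexes: Optional[Sequence[str]] = None,
    cohorts: Optional[Sequence[int]] = None,
    age_bins: Optional[np.ndarray] = None,
    evaluator: Optional[HazardEvaluator] = None,
) -> pd.DataFrame:
    """Poisson-sampled registry-style incidence table from ground truth.

    For each (sex, cohort, age bin): cases ~ Poisson(PY * rate) with the
    rate evaluated at the bin midpoint under the configuration's
    parameters.  ``py_per_stratum`` is the person-years observed in each
    calibration stratum, i.e. each table row, matching the registry
    convention of per-bin exposure.  Ground truth and seed are attached
    in ``DataFrame.attrs['metadata']``.
    """
    if py_per_stratum <= 0:
        raise InputError("py_per_stratum must be > 0")
    sexes = list(sexes) if sexes is not None else cfg.sexes
    cohorts = list(cohorts) if cohorts is not None else sorted(cfg.cohort_multipliers)
    bins = np.asarray(age_bins if age_bins is not None else default_age_bins(), float)
    if bins.size < 2 or not np.all(np.diff(bins) > 0):
        raise InputError("age_bins must be strictly increasing with >= 2 edges")
    evaluator = evaluator or HazardEvaluator(cfg)
    rng = np.random.default_rng(seed)
    py_bin = float(py_per_stratum)
    rows = []
    for sex in sexes:
        for cohort in cohorts:
            curve = evaluator.curve(sex, cohort)
            mids = 0.5 * (bins[:-1] + bins[1:])
            rates = curve.hazard_at(mids)
            if not np.all(np.isfinite(rates)):
                raise InputError(
                    f"analytic rate unavailable for stratum ({sex}, {cohort})"
                )
            cases = rng.poisson(py_bin * rates)
            for lo, hi, c in zip(bins[:-1], bins[1:], cases):
                rows.append(
                    {
                        "sex": sex,
                        "cohort": cohort,
                        "age_low": lo,
                        "age_high": hi,
                        "cases": int(c),
                        "person_years": py_bin,
                    }
                )
    table = pd.DataFrame(rows)
    table.attrs["metadata"] = {
        "seed": int(seed),
        "py_per_stratum": float(py_per_stratum),
        "truth": {
            "biology": cfg.biology().to_dict(),
            "nu0": {s: cfg.nu0(s) for s in sexes},
            "cohort_multipliers": cfg.cohort_multipliers,
            "rr": cfg.gerd().rr,
        },
    }
    return table


def make_screening_cohort(
    n: int,
    cfg: Config,
    seed: int,
    age_range: tuple[int, int] = (40, 80),
    sexes: Sequence[str] = ("M", "F"),
    cohort: Optional[int] = None,
    evaluator: Optional[HazardEvaluator] = None,
) -> pd.DataFrame:
    """Screening-yield cohort: BE found in sampled cancer-free persons.

    Ages are sampled uniformly on ``age_range``, sex uniformly from
    ``sexes``, GERD status Bernoulli(p_GERD(age)), and BE status
    Bernoulli(p_be_cf) with the cancer-free BE prevalence of the
    individual's GERD subgroup.  Columns: age, sex, gerd, be_found.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    if not sexes:
        raise InputError("sampling spec needs at least one sex")
    lo, hi = age_range
    if not lo <= hi:
        raise InputError("age_range must satisfy lo <= hi")
    evaluator = evaluator or HazardEvaluator(cfg)
    if cohort is None:
        cohort = max(cfg.cohort_multipliers) if cfg.cohort_multipliers else None
    rng = np.random.default_rng(seed)
    age = rng.integers(lo, hi + 1, size=n)
    sex = np.asarray(sexes)[rng.integers(0, len(sexes), size=n)]
    rows = {"age": age, "sex": sex}
    gerd = np.zeros(n, dtype=bool)
    be_found = np.zeros(n, dtype=bool)
    for s in sexes:
        mask = sex == s
        p_gerd = cfg.gerd(s).prevalence(age[mask])
        gerd[mask] = rng.random(mask.sum()) < p_gerd
        for flag, subgroup in ((True, "gerd"), (False, "non_gerd")):
            sub = mask & (gerd == flag)
            if not sub.any():
                continue
            curve = evaluator.curve(s, cohort, subgroup=subgroup)
            p_be = curve.prevalence_at(age[sub])
            be_found[sub] = rng.random(sub.sum()) < p_be
    rows["gerd"] = gerd
    rows["be_found"] = be_found
    out = pd.DataFrame(rows)
    out.attrs["metadata"] = {"seed": int(seed), "cohort": cohort}
    return out
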