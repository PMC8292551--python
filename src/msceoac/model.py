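"""Cached hazard-curve evaluation for calibration and projection.

``HazardEvaluator`` turns a configuration (plus optional named parameter
overrides) into :class:`~msceoac.hazard.HazardCurve` objects per
(sex, cohort, subgroup) stratum.  The expensive backward-ODE solve and the
segment-length marginalisation depend only on the biological parameters,
so they are cached and shared across strata and across calibration steps
that vary only onset-side parameters.

Recognised override names:

* ``nu0`` (all sexes) or ``nu0_<sex>`` e.g. ``nu0_M``
* any biological rate: ``mu0``, ``mu1``, ``mu2``, ``alphaP``, ``betaP``,
  ``alphaM``, ``betaM``, ``rho`` (``mu0`` also sets ``mu1`` when the
  calibration config ties them)
* ``cohort_<year>`` e.g. ``cohort_1940`` for a cohort multiplier
* ``rr`` for the GERD relative risk
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np

from .config import Config
from .errors import InputError
from .hazard import BeSurvival, HazardCurve, be_survival, population_hazard, solve_backward_system
from .onset import BeOnsetModel
from .params import BiologicalParams

__all__ = ["HazardEvaluator", "apply_overrides"]

_BIO_NAMES = {"mu0", "mu1", "mu2", "alphaP", "betaP", "alphaM", "betaM", "rho"}


def apply_overrides(cfg: Config, overrides: Optional[Mapping[str, float]]) -> Config:
    """Return a config with named parameter overrides applied."""
    if not overrides:
        return cfg
    patch: dict = {}
    bio: dict = {}
    onset_nu0: dict = {}
    multipliers: dict = {}
    tie = bool(cfg.calibration.get("tie_mu01", True))
    for name, value in overrides.items():
        value = float(value)
        if name in _BIO_NAMES:
            bio[name] = value
            if name == "mu0" and tie and "mu1" not in overrides:
                bio["mu1"] = value
        elif name == "nu0":
            for sex in cfg.sexes:
                onset_nu0[sex] = value
        elif name.startswith("nu0_"):
            onset_nu0[name[4:]] = value
        elif name.startswith("cohort_"):
            multipliers[int(name[7:])] = value
        elif name == "rr":
            patch.setdefault("gerd", {})["rr"] = value
        else:
            raise InputError(f"unknown parameter override {name!r}")
    if bio:
        patch["biology"] = bio
    if onset_nu0 or multipliers:
        patch["onset"] = {}
        if onset_nu0:
            base = cfg.raw["onset"]["nu0"]
            merged = dict(base) if isinstance(base, Mapping) else {s: base for s in cfg.sexes}
            merged.update(onset_nu0)
            patch["onset"]["nu0"] = merged
        if multipliers:
            merged_m = dict(cfg.raw["onset"]["cohort_multipliers"])
            merged_m.update({k: v for k, v in multipliers.items()})
            patch["onset"]["cohort_multipliers"] = merged_m
    # skip full re-validation on this hot path: override values are
    # validated where they are consumed (BiologicalParams, BeOnsetModel)
    from .config import Config, _deep_merge

    return Config(raw=_deep_merge(cfg.raw, patch))


class HazardEvaluator:
    """Builds and caches hazard curves for a configuration."""

    def __init__(self, cfg: Config):
        self.cfg = cfg
        self._age_grid = cfg.age_grid()
        self._be_surv_cache: dict[tuple, BeSurvival] = {}
        self._curve_cache: dict[tuple, HazardCurve] = {}

    @property
    def age_grid(self) -> np.ndarray:
        return self._age_grid

    def _be_surv(self, cfg: Config) -> BeSurvival:
        bio = cfg.biology()
        seg = cfg.segment()
        key = (
            tuple(sorted(bio.to_dict().items())),
            tuple(sorted(seg.to_dict().items())),
        )
        cached = self._be_surv_cache.get(key)
        if cached is None:
            solution = solve_backward_system(bio, self._age_grid)
            cached = be_survival(solution, seg)
            if len(self._be_surv_cache) > 64:
                self._be_surv_cache.clear()
            self._be_surv_cache[key] = cached
        return cached

    def curve(
        self,
        sex: str,
        cohort: Optional[int] = None,
        subgroup: str = "population",
        overrides: Optional[Mapping[str, float]] = None,
    ) -> HazardCurve:
        """Hazard curve for one stratum under optional overrides."""
        key = (
            sex,
            cohort,
            subgroup,
            tuple(sorted(overrides.items())) if overrides else (),
        )
        cached = self._curve_cache.get(key)
        if cached is not None:
            return cached
        cfg = apply_overrides(self.cfg, overrides)
        be_surv = self._be_surv(cfg)
        onset = cfg.onset_model(sex, cohort)
        curve = population_hazard(
            be_surv, onset, self._age_grid, subgroup=subgroup, sex=sex, cohort=cohort
        )
        if len(self._curve_cache) > 512:
            self._curve_cache.clear()
        self._curve_cache[key] = curve
        return curve

    def onset_model(
        self,
        sex: str,
        cohort: Optional[int] = None,
        overrides: Optional[Mapping[str, float]] = None,
    ) -> BeOnsetModel:
        return apply_overrides(self.cfg, overrides).onset_model(sex, cohort)
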