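"""Configuration: defaults, validation, and typed accessors.

A configuration is a nested mapping (YAML/JSON on disk).  ``load_config``
applies defaults, rejects unknown keys, validates invariants and returns a
:class:`Config`.  The packaged demo configuration is a complete
ground-truth parameter set for the synthetic-data generators; its values
are chosen to echo the order of magnitude of US oesophageal-adenocarcinoma
epidemiology (lifetime risk ~1% in men, cancer-free BE prevalence 1-2% by
age 60, male:female baseline conversion 4:1) and are not estimates from
any registry.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import yaml

from .errors import ConfigError
from .onset import BeOnsetModel, GerdModel
from .params import BeSegmentModel, BiologicalParams

__all__ = ["Config", "load_config", "dump_config", "demo_config"]

_DATA_DIR = Path(__file__).parent / "data"

# Schema: nested mapping key -> either a dict (subsection) or None (leaf).
_SCHEMA: dict[str, Any] = {
    "seed": None,
    "grid": {"step": None, "max_age": None},
    "age_range": None,
    "biology": {k: None for k in ("mu0", "mu1", "alphaP", "betaP", "mu2", "alphaM", "betaM", "rho")},
    "segment": {k: None for k in ("beta_a", "beta_b", "length_max", "cells_per_cm", "n_quad")},
    "onset": {"nu0": None, "cohort_multipliers": None},
    "gerd": {"rr": None, "curve": {"p_max": None, "k": None, "t0": None}, "table": None},
    "calibration": {
        "free": None,
        "n_starts": None,
        "maxiter": None,
        "tol": None,
        "seed": None,
        "tie_mu01": None,
        "bounds": None,
        "n_draws": None,
    },
}


def _check_keys(d: Mapping, schema: Mapping, path: str = "") -> None:
    for key, value in d.items():
        if key not in schema:
            valid = sorted(schema)
            raise ConfigError(
                f"unknown config key {path + key!r}; valid keys here: {valid}"
            )
        sub = schema[key]
        if isinstance(sub, dict) and isinstance(value, Mapping):
            _check_keys(value, sub, path + key + ".")


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass(frozen=True)
class Config:
    """Validated configuration with typed accessors."""

    raw: dict

    # -- typed views ------------------------------------------------
    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def grid_step(self) -> float:
        return float(self.raw["grid"]["step"])

    @property
    def max_age(self) -> float:
        return float(self.raw["grid"]["max_age"])

    @property
    def age_range(self) -> tuple[int, int]:
        lo, hi = self.raw["age_range"]
        return int(lo), int(hi)

    def age_grid(self) -> np.ndarray:
        n = int(round(self.max_age / self.grid_step))
        return np.linspace(0.0, n * self.grid_step, n + 1)

    def biology(self) -> BiologicalParams:
        return BiologicalParams.from_dict(self.raw["biology"])

    def segment(self) -> BeSegmentModel:
        return BeSegmentModel.from_dict(self.raw["segment"])

    def gerd(self, sex: str = "M") -> GerdModel:
        g = self.raw["gerd"]
        rr = float(g["rr"])
        curve = g.get("curve")
        if curve is not None:
            c = curve.get(sex, curve) if set(curve) <= {"M", "F"} else curve
            return GerdModel.from_logistic(float(c["p_max"]), float(c["k"]), float(c["t0"]), rr=rr)
        table = g.get("table")
        if table is None:
            raise ConfigError("gerd config needs either 'curve' or 'table'")
        import pandas as pd

        df = pd.read_csv(table)
        sub = df[df["sex"] == sex]
        return GerdModel.from_table(sub["age"], sub["prevalence"], rr=rr)

    def nu0(self, sex: str) -> float:
        nu0 = self.raw["onset"]["nu0"]
        if isinstance(nu0, Mapping):
            if sex not in nu0:
                raise ConfigError(f"no nu0 configured for sex {sex!r}")
            return float(nu0[sex])
        return float(nu0)

    @property
    def sexes(self) -> list[str]:
        nu0 = self.raw["onset"]["nu0"]
        return sorted(nu0) if isinstance(nu0, Mapping) else ["M", "F"]

    @property
    def cohort_multipliers(self) -> dict[int, float]:
        return {int(k): float(v) for k, v in self.raw["onset"]["cohort_multipliers"].items()}

    def onset_model(self, sex: str, cohort: Optional[int] = None) -> BeOnsetModel:
        return BeOnsetModel(
            nu0=self.nu0(sex),
            gerd=self.gerd(sex),
            cohort_multipliers=self.cohort_multipliers,
            sex=sex,
            cohort=cohort,
            grid_step=self.grid_step,
        )

    @property
    def calibration(self) -> dict:
        return self.raw["calibration"]

    def updated(self, override: Mapping) -> "Config":
        merged = _deep_merge(self.raw, override)
        return _validate(merged)

    def to_dict(self) -> dict:
        return copy.deepcopy(self.raw)


def _validate(raw: dict) -> Config:
    _check_keys(raw, _SCHEMA)
    cfg = Config(raw=raw)
    # touch the typed views so invariants fire at load time
    cfg.biology()
    cfg.segment()
    for sex in cfg.sexes:
        cfg.gerd(sex)
        if cfg.nu0(sex) < 0:
            raise ConfigError(f"nu0 for sex {sex!r} must be >= 0")
    if cfg.grid_step <= 0 or cfg.max_age <= 0:
        raise ConfigError("grid.step and grid.max_age must be > 0")
    lo, hi = cfg.age_range
    if not (0 <= lo < hi <= cfg.max_age):
        raise ConfigError(
            f"age_range {cfg.age_range} must satisfy 0 <= lo < hi <= max_age"
        )
    for c, m in cfg.cohort_multipliers.items():
        if m <= 0:
            raise ConfigError(f"cohort multiplier for {c} must be > 0")
    return cfg


def demo_config() -> Config:
    """The packaged demo / ground-truth configuration."""
    with open(_DATA_DIR / "demo_config.yaml") as fh:
        raw = yaml.safe_load(fh)
    return _validate(raw)


def load_config(path: Optional[str] = None) -> Config:
    """Load a config file, applying demo defaults for missing keys.

    ``path=None`` (or an empty file) returns the full default set.
    """
    base = demo_config().raw
    if path is None:
        return _validate(base)
    with open(path) as fh:
        user = yaml.safe_load(fh)
    if user is None:
        user = {}
    if not isinstance(user, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    _check_keys(user, _SCHEMA)
    return _validate(_deep_merge(base, user))


def dump_config(cfg: Config, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
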