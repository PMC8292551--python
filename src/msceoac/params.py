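"""Biological rate parameters and the Barrett's-segment length model.

All rates are per cell per year.  The cell-level process after Barrett's
oesophagus (BE) onset is a two-hit initiation (rates ``mu0``, ``mu1``)
followed by clonal expansion of premalignant cells (birth ``alphaP``,
death/differentiation ``betaP``), malignant transformation (``mu2``),
malignant clonal growth (``alphaM``, ``betaM``) and size-based clinical
detection (per-malignant-cell rate ``rho``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import stats
from scipy.special import roots_legendre

from .errors import ConfigError

__all__ = ["BiologicalParams", "BeSegmentModel"]

_RATE_FIELDS = ("mu0", "mu1", "alphaP", "betaP", "mu2", "alphaM", "betaM", "rho")


@dataclass(frozen=True)
class BiologicalParams:
    """Per-cell per-year rates of the clonal-expansion process.

    Parameters
    ----------
    mu0, mu1
        First and second hit rates of the two-hit initiation of a
        premalignant clone (per BE stem cell, per one-hit cell).
    alphaP, betaP
        Division and death/differentiation rates of premalignant cells.
    mu2
        Malignant transformation rate per premalignant cell.
    alphaM, betaM
        Division and death/differentiation rates of malignant cells.
    rho
        Detection rate per malignant cell; a clone of ``n`` cells is
        detected at rate ``n * rho`` (size-based detection).
    """

    mu0: float
    mu1: float
    alphaP: float
    betaP: float
    mu2: float
    alphaM: float
    betaM: float
    rho: float

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ConfigError(
                    f"BiologicalParams.{name} must be finite and >= 0, got {value!r}"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BiologicalParams":
        unknown = set(d) - set(_RATE_FIELDS)
        if unknown:
            raise ConfigError(
                f"unknown biological parameter(s) {sorted(unknown)}; "
                f"valid keys: {list(_RATE_FIELDS)}"
            )
        missing = set(_RATE_FIELDS) - set(d)
        if missing:
            raise ConfigError(f"missing biological parameter(s) {sorted(missing)}")
        return cls(**{k: float(d[k]) for k in _RATE_FIELDS})

    def replace(self, **kwargs) -> "BiologicalParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BeSegmentModel:
    """Beta-distributed BE segment length and the stem-cell scaling.

    Segment length L ~ length_max * Beta(beta_a, beta_b) in cm; the number
    of BE stem cells at risk is ``N(L) = cells_per_cm * L`` (continuous,
    by independence of cells the survival exponent need not be integer).
    """

    beta_a: float = 2.0
    beta_b: float = 6.0
    length_max: float = 10.0
    cells_per_cm: float = 100.0
    n_quad: int = 16

    def __post_init__(self) -> None:
        for name in ("beta_a", "beta_b", "length_max", "cells_per_cm"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ConfigError(
                    f"BeSegmentModel.{name} must be finite and > 0, got {value!r}"
                )
        if self.n_quad < 2:
            raise ConfigError("BeSegmentModel.n_quad must be >= 2")

    def mean_length(self) -> float:
        """Mean segment length in cm (helper for config sanity checks)."""
        return self.beta_a / (self.beta_a + self.beta_b) * self.length_max

    def length_distribution(self):
        """The scipy frozen Beta law of L on [0, length_max]."""
        return stats.beta(self.beta_a, self.beta_b, loc=0.0, scale=self.length_max)

    def quadrature(self) -> tuple[np.ndarray, np.ndarray]:
        """Fixed Gauss–Legendre nodes (lengths, weights) for E_L[.].

        Weights are renormalised to sum to exactly 1 so that the
        marginalisation preserves probability mass.
        """
        x, w = roots_legendre(self.n_quad)
        lengths = 0.5 * (x + 1.0) * self.length_max
        pdf = self.length_distribution().pdf(lengths)
        weights = w * pdf
        total = weights.sum()
        if total <= 0:
            raise ConfigError(
                "degenerate length quadrature: all weights are zero"
            )
        return lengths, weights / total

    def stem_cells(self, length) -> np.ndarray:
        return self.cells_per_cm * np.asarray(length, dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BeSegmentModel":
        valid = {"beta_a", "beta_b", "length_max", "cells_per_cm", "n_quad"}
        unknown = set(d) - valid
        if unknown:
            raise ConfigError(
                f"unknown segment parameter(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        return cls(**d)
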