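"""Exact stochastic simulation of individual OAC natural histories.

Serves as the independent oracle for the analytic hazard engine: identical
model semantics (parent-persists spawning, size-based detection), simulated
event-by-event.  BE onset is drawn by inverting the cumulative onset hazard
of the requested subgroup; after onset a Gillespie loop with aggregated
per-compartment propensities runs over one-hit, premalignant and malignant
cell counts until detection or ``max_age``.

Randomness: every individual gets a named substream derived from
``(master seed, index)`` via :class:`numpy.random.SeedSequence`, so cohort
histories are reproducible and independent of simulation order.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SimulationError
from .onset import BeOnsetModel, onset_rate
from .params import BeSegmentModel, BiologicalParams

__all__ = [
    "IndividualHistory",
    "simulate_individual",
    "simulate_cohort",
    "empirical_incidence",
    "histories_to_frame",
]

EVENT_CAP = 10_000_000  # safety cap on Gillespie events per individual


@dataclass(frozen=True)
class IndividualHistory:
    """One simulated life history."""

    sex: str
    cohort: Optional[int]
    gerd_onset_age: Optional[float]
    be_onset_age: Optional[float]
    be_length: Optional[float]
    n_stem_cells: Optional[float]
    oac_detection_age: Optional[float]
    seed: int
    index: int = 0

    def __post_init__(self) -> None:
        if self.oac_detection_age is not None:
            if self.be_onset_age is None:
                raise SimulationError("detection recorded without BE onset")
            if self.oac_detection_age <= self.be_onset_age:
                raise SimulationError("detection age must exceed BE onset age")


class _InversionTables:
    """Shared inversion tables for BE onset and GERD onset draws."""

    def __init__(self, onset: BeOnsetModel, max_age: float, subgroup: str):
        step = onset.grid_step
        n = max(2, int(np.ceil(max_age / step)) + 1)
        self.ages = np.linspace(0.0, max_age, n)
        nu = onset_rate(onset, self.ages, subgroup)
        self.lam = np.concatenate(
            ([0.0], np.cumsum(0.5 * (nu[1:] + nu[:-1]) * np.diff(self.ages)))
        )
        self.p_gerd = onset.gerd.prevalence(self.ages)
        self.subgroup = subgroup

    def be_onset(self, exp_draw: float) -> Optional[float]:
        if exp_draw >= self.lam[-1]:
            return None
        return float(np.interp(exp_draw, self.lam, self.ages))

    def gerd_onset(self, unif_draw: float) -> Optional[float]:
        if self.subgroup == "gerd":
            return 0.0
        if self.subgroup == "non_gerd":
            return None
        if unif_draw >= self.p_gerd[-1]:
            return None
        return float(np.interp(unif_draw, self.p_gerd, self.ages))


def _substream_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence((int(seed), int(index))).generate_state(1)[0])


def _run_gillespie(
    rnd: random.Random,
    params: BiologicalParams,
    n_stem: float,
    t_start: float,
    max_age: float,
) -> Optional[float]:
    """Event loop over cell-count compartments; returns detection age or None."""
    if 0.0 in (params.rho, params.mu0, params.mu1, params.mu2):
        return None  # detection unreachable; exact shortcut
    mu0, mu1, mu2 = params.mu0, params.mu1, params.mu2
    a_p, b_p = params.alphaP, params.betaP
    a_m, b_m, rho = params.alphaM, params.betaM, params.rho
    c_p = a_p + b_p + mu2
    c_m = a_m + b_m + rho
    spawn1 = n_stem * mu0

    t = t_start
    n1 = 0
    n_p = 0
    n_m = 0
    events = 0
    expovariate = rnd.expovariate
    uniform = rnd.random
    while True:
        r1 = n1 * mu1
        r_p = n_p * c_p
        r_m = n_m * c_m
        total = spawn1 + r1 + r_p + r_m
        if total <= 0.0:
            return None
        t += expovariate(total)
        if t >= max_age:
            return None
        events += 1
        if events > EVENT_CAP:
            raise SimulationError(
                f"event cap {EVENT_CAP} exceeded (params={params.to_dict()}, "
                f"n_stem={n_stem:.1f}, t={t:.2f})"
            )
        u = uniform() * total
        if u < spawn1:
            n1 += 1
        elif u < spawn1 + r1:
            n_p += 1
        elif u < spawn1 + r1 + r_p:
            v = u - (spawn1 + r1)
            if v < n_p * a_p:
                n_p += 1
            elif v < n_p * (a_p + b_p):
                n_p -= 1
            else:
                n_m += 1
        else:
            v = u - (spawn1 + r1 + r_p)
            if v < n_m * a_m:
                n_m += 1
            elif v < n_m * (a_m + b_m):
                n_m -= 1
            else:
                return t  # detection


def simulate_individual(
    params: BiologicalParams,
    onset: BeOnsetModel,
    segment: BeSegmentModel,
    max_age: float,
    seed: int,
    index: int = 0,
    subgroup: str = "population",
    _tables: Optional[_InversionTables] = None,
) -> IndividualHistory:
    """Simulate one individual; deterministic given ``(seed, index)``."""
    if max_age <= 0:
        raise InputError("max_age must be > 0")
    tables = _tables or _InversionTables(onset, max_age, subgroup)
    rnd = random.Random(_substream_seed(seed, index))

    gerd_onset = tables.gerd_onset(rnd.random())
    be_onset_age = tables.be_onset(rnd.expovariate(1.0))

    be_length = n_stem = detection = None
    if be_onset_age is not None:
        be_length = rnd.betavariate(segment.beta_a, segment.beta_b) * segment.length_max
        n_stem = segment.cells_per_cm * be_length
        detection = _run_gillespie(rnd, params, n_stem, be_onset_age, max_age)

    return IndividualHistory(
        sex=onset.sex,
        cohort=onset.cohort,
        gerd_onset_age=gerd_onset,
        be_onset_age=be_onset_age,
        be_length=be_length,
        n_stem_cells=n_stem,
        oac_detection_age=detection,
        seed=int(seed),
        index=int(index),
    )


def simulate_cohort(
    n: int,
    params: BiologicalParams,
    onset: BeOnsetModel,
    segment: BeSegmentModel,
    max_age: float,
    seed: int,
    subgroup: str = "population",
) -> list[IndividualHistory]:
    """Simulate ``n`` independent histories from seed-derived substreams."""
    if n < 1:
        raise InputError("n must be >= 1")
    tables = _InversionTables(onset, max_age, subgroup)
    out = []
    for i in range(n):
        try:
            out.append(
                simulate_individual(
                    params, onset, segment, max_age, seed,
                    index=i, subgroup=subgroup, _tables=tables,
                )
            )
        except SimulationError as exc:
            raise SimulationError(f"individual {i}: {exc}") from exc
    return out


def histories_to_frame(histories: Sequence[IndividualHistory]) -> pd.DataFrame:
    """One row per individual, suitable for CSV export."""
    return pd.DataFrame([asdict(h) for h in histories])


def empirical_incidence(
    histories: Sequence[IndividualHistory],
    age_bins: Sequence[float],
    max_age: Optional[float] = None,
) -> pd.DataFrame:
    """Cases and person-years per age bin, as a registry-style table.

    Person-years accrue until OAC detection or ``max_age``; each case is
    counted in the bin containing its detection age.  Output columns match
    the incidence-table schema (sex, cohort, age_low, age_high, cases,
    person_years).
    """
    if not histories:
        raise InputError("empty cohort")
    bins = np.asarray(age_bins, dtype=float)
    if bins.ndim != 1 or bins.size < 2 or not np.all(np.diff(bins) > 0):
        raise InputError("age_bins must be strictly increasing with >= 2 edges")

    det = np.array(
        [np.inf if h.oac_detection_age is None else h.oac_detection_age for h in histories]
    )
    if max_age is None:
        max_age = float(bins[-1])
    end = np.minimum(det, max_age)

    frames = []
    keys = sorted({(h.sex, h.cohort) for h in histories}, key=lambda k: (k[0], str(k[1])))
    for sex, cohort in keys:
        mask = np.array([(h.sex, h.cohort) == (sex, cohort) for h in histories])
        e = end[mask]
        d = det[mask]
        rows = []
        for lo, hi in zip(bins[:-1], bins[1:]):
            py = float(np.sum(np.clip(e - lo, 0.0, hi - lo)))
            cases = int(np.sum((d >= lo) & (d < hi)))
            rows.append(
                {
                    "sex": sex,
                    "cohort": cohort if cohort is not None else "",
                    "age_low": lo,
                    "age_high": hi,
                    "cases": cases,
                    "person_years": py,
                }
            )
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)
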