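"""Poisson-likelihood calibration to stratified incidence tables.

The unit of calibration is a registry-style table of (sex, birth cohort,
age bin) rows with observed case counts and person-years.  For each row
the model rate is the hazard at the bin midpoint, the expected count is
``lambda = person_years * rate`` and the log likelihood is the sum of
Poisson terms ``c ln(lambda) - lambda - ln(c!)``.  Maximisation is by
multi-start Nelder–Mead in log-parameter space; nested stratifications
are compared with likelihood-ratio tests, and parameter uncertainty comes
from draws of the asymptotic normal approximation with the observed
information, with a nonparametric bootstrap fallback when the information
matrix is singular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .errors import ConfigError, FitError, InputError
from .model import HazardEvaluator

__all__ = [
    "FitSpec",
    "FitResult",
    "poisson_loglik",
    "fit_model",
    "likelihood_ratio_test",
    "parameter_uncertainty",
]

logger = logging.getLogger(__name__)

_ZERO_RATE_PENALTY = -1e10  # guard for lambda == 0 with observed cases


def _bounds_key(name: str) -> str:
    if name.startswith("nu0"):
        return "nu0"
    if name.startswith("cohort_"):
        return "cohort_multiplier"
    return name


@dataclass(frozen=True)
class FitSpec:
    """Free-parameter list, bounds and optimizer settings for one fit."""

    free: tuple[str, ...]
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    n_starts: int = 5
    maxiter: int = 2000
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.free:
            raise InputError("FitSpec.free must be non-empty")
        if len(set(self.free)) != len(self.free):
            raise InputError("FitSpec.free contains duplicates")

    def bound(self, name: str) -> tuple[float, float]:
        key = _bounds_key(name)
        if name in self.bounds:
            lo, hi = self.bounds[name]
        elif key in self.bounds:
            lo, hi = self.bounds[key]
        else:
            raise ConfigError(f"no bounds configured for parameter {name!r}")
        return float(lo), float(hi)

    @classmethod
    def from_config(cls, cfg, free: Sequence[str], **overrides) -> "FitSpec":
        cal = cfg.calibration
        kw = dict(
            bounds={k: tuple(v) for k, v in (cal.get("bounds") or {}).items()},
            n_starts=int(cal.get("n_starts", 5)),
            maxiter=int(cal.get("maxiter", 2000)),
            tol=float(cal.get("tol", 1e-8)),
            seed=int(cal.get("seed", 0)),
        )
        kw.update(overrides)
        return cls(free=tuple(free), **kw)


@dataclass
class FitResult:
    """Calibration result with convergence metadata."""

    estimates: dict[str, float]
    loglik: float
    n_free: int
    spec: FitSpec
    status: str
    n_iter: int
    n_evals: int
    at_bound: tuple[str, ...] = ()
    covariance: Optional[np.ndarray] = None
    covariance_source: Optional[str] = None
    _loglik_fn: Optional[Callable[[Mapping[str, float]], float]] = None
    _table: Optional[pd.DataFrame] = None
    _evaluator: Optional[HazardEvaluator] = None

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(self.spec.free)

    def summary(self) -> dict:
        return {
            "estimates": self.estimates,
            "loglik": self.loglik,
            "n_free": self.n_free,
            "status": self.status,
            "n_iter": self.n_iter,
            "n_evals": self.n_evals,
            "at_bound": list(self.at_bound),
            "seed": self.spec.seed,
        }


def _strata(table: pd.DataFrame):
    for (sex, cohort), group in table.groupby(["sex", "cohort"], sort=True):
        yield sex, int(cohort), group


def poisson_loglik(
    overrides: Mapping[str, float],
    table: pd.DataFrame,
    evaluator: HazardEvaluator,
) -> float:
    """Poisson log likelihood of an incidence table at given parameters.

    ``overrides`` maps parameter names (see :mod:`msceoac.model`) to
    values layered on top of the evaluator's configuration.
    """
    total = 0.0
    for sex, cohort, group in _strata(table):
        curve = evaluator.curve(sex, cohort, overrides=dict(overrides))
        mid = 0.5 * (group["age_low"].to_numpy() + group["age_high"].to_numpy())
        lam = group["person_years"].to_numpy() * curve.hazard_at(mid)
        cases = group["cases"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(
                lam > 0.0,
                cases * np.log(np.maximum(lam, 1e-300)) - lam - gammaln(cases + 1.0),
                np.where(cases > 0, _ZERO_RATE_PENALTY, 0.0),
            )
        total += float(terms.sum())
    return total


def fit_model(
    table: pd.DataFrame,
    spec: FitSpec,
    evaluator: HazardEvaluator,
) -> FitResult:
    """Maximise the Poisson likelihood by multi-start Nelder–Mead.

    Optimisation runs in log-parameter space with soft penalties outside
    the configured bounds; deterministic given ``spec.seed``.
    """
    if table.empty:
        raise InputError("incidence table is empty")
    free = list(spec.free)
    lo = np.array([spec.bound(name)[0] for name in free])
    hi = np.array([spec.bound(name)[1] for name in free])
    log_lo, log_hi = np.log(lo), np.log(hi)

    n_evals = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        clipped = np.clip(x, log_lo, log_hi)
        penalty = 1e8 * float(np.sum((x - clipped) ** 2))
        values = dict(zip(free, np.exp(clipped)))
        return -poisson_loglik(values, table, evaluator) + penalty

    rng = np.random.default_rng(spec.seed)
    cfg = evaluator.cfg
    starts = []
    # start 0: current config values, clipped into bounds
    x0 = []
    for name in free:
        if name.startswith("nu0_"):
            v = cfg.nu0(name[4:])
        elif name == "nu0":
            v = cfg.nu0(cfg.sexes[0])
        elif name.startswith("cohort_"):
            v = cfg.cohort_multipliers.get(int(name[7:]), 1.0)
        else:
            v = getattr(cfg.biology(), name)
        x0.append(np.clip(v if v > 0 else np.sqrt(lo[len(x0)] * hi[len(x0)]), None, None))
    starts.append(np.log(np.clip(np.array(x0, dtype=float), lo, hi)))
    for _ in range(max(0, spec.n_starts - 1)):
        starts.append(rng.uniform(log_lo, log_hi))

    best = None
    n_iter_total = 0
    for start in starts:
        res = optimize.minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={
                "maxiter": spec.maxiter,
                "fatol": spec.tol,
                "xatol": 1e-8,
                "adaptive": len(free) > 2,
            },
        )
        n_iter_total += res.nit
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(
            f"calibration failed after {spec.n_starts} restarts "
            f"(best objective {None if best is None else best.fun!r})"
        )

    x_hat = np.clip(best.x, log_lo, log_hi)
    theta = np.exp(x_hat)
    at_bound = tuple(
        name
        for name, v, l, h in zip(free, theta, lo, hi)
        if v <= l * (1 + 1e-6) or v >= h * (1 - 1e-6)
    )
    if at_bound:
        logger.warning("parameters at bounds: %s", at_bound)
    estimates = dict(zip(free, (float(v) for v in theta)))
    loglik = poisson_loglik(estimates, table, evaluator)
    status = "converged" if best.success else "maxiter"

    return FitResult(
        estimates=estimates,
        loglik=float(loglik),
        n_free=len(free),
        spec=spec,
        status=status,
        n_iter=n_iter_total,
        n_evals=n_evals,
        at_bound=at_bound,
        _loglik_fn=lambda values: poisson_loglik(values, table, evaluator),
        _table=table,
        _evaluator=evaluator,
    )


def likelihood_ratio_test(
    fit_null: FitResult, fit_alt: FitResult
) -> tuple[float, int, float]:
    """LRT of a nested null against an alternative stratification.

    Returns ``(statistic, df, p)`` with the statistic clipped at zero and
    the p-value from the chi-square upper tail.  Nesting is validated
    structurally: the alternative must have strictly more free
    parameters.
    """
    df = fit_alt.n_free - fit_null.n_free
    if df <= 0:
        raise InputError(
            "fit_alt must have strictly more free parameters than fit_null "
            f"(got {fit_alt.n_free} vs {fit_null.n_free})"
        )
    stat = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def _observed_information(fit: FitResult) -> np.ndarray:
    """Negative Hessian of the log likelihood at the estimates, by central
    finite differences on the natural scale."""
    names = list(fit.param_names)
    theta = np.array([fit.estimates[n] for n in names])
    f = fit._loglik_fn
    steps = np.maximum(1e-4 * np.abs(theta), 1e-12)

    def ll(vec):
        return f(dict(zip(names, vec)))

    k = len(names)
    hess = np.empty((k, k))
    f0 = ll(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        fpp = ll(theta + ei)
        fmm = ll(theta - ei)
        hess[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = steps[j]
            fij = ll(theta + ei + ej) - ll(theta + ei - ej) - ll(theta - ei + ej) + ll(theta - ei - ej)
            hess[i, j] = hess[j, i] = fij / (4 * steps[i] * steps[j])
    return -hess


def parameter_uncertainty(
    fit: FitResult,
    n_draws: int = 1000,
    seed: int = 0,
    n_bootstrap: int = 50,
) -> pd.DataFrame:
    """Parameter draws from the asymptotic normal approximation.

    Samples ``n_draws`` vectors from N(theta_hat, I^-1) truncated to the
    feasible region; deterministic given ``seed``.  A singular information
    matrix triggers a nonparametric bootstrap over table rows (the
    fallback is logged).
    """
    if fit.status not in ("converged", "maxiter"):
        raise FitError(f"cannot draw from a fit with status {fit.status!r}")
    names = list(fit.param_names)
    theta = np.array([fit.estimates[n] for n in names])
    lo = np.array([fit.spec.bound(n)[0] for n in names])
    hi = np.array([fit.spec.bound(n)[1] for n in names])
    rng = np.random.default_rng(seed)

    cov = None
    try:
        info = _observed_information(fit)
        cov = np.linalg.inv(info)
        # symmetrise and check positive semidefiniteness
        cov = 0.5 * (cov + cov.T)
        eigvals = np.linalg.eigvalsh(cov)
        if np.any(eigvals < -1e-12 * max(1.0, eigvals.max())):
            raise np.linalg.LinAlgError("covariance not PSD")
        cov = cov + np.eye(len(names)) * max(0.0, -eigvals.min() + 0.0)
        fit.covariance = cov
        fit.covariance_source = "observed_information"
    except np.linalg.LinAlgError as exc:
        logger.warning("information matrix unusable (%s); bootstrap fallback", exc)
        fit.covariance_source = "bootstrap"

    if fit.covariance_source == "observed_information":
        draws = np.empty((0, len(names)))
        n_reject = 0
        while draws.shape[0] < n_draws:
            batch = rng.multivariate_normal(theta, cov, size=n_draws, method="svd")
            ok = np.all((batch >= lo) & (batch <= hi), axis=1)
            n_reject += int((~ok).sum())
            draws = np.vstack([draws, batch[ok]])
            if n_reject > 50 * n_draws:
                raise FitError(
                    ">50x rejection drawing within bounds; interval undefined"
                )
        draws = draws[:n_draws]
        if n_reject:
            logger.info("rejected %d out-of-bounds draws", n_reject)
    else:
        table = fit._table
        evaluator = fit._evaluator
        if table is None or evaluator is None:
            raise FitError("bootstrap fallback needs the original table")
        boot = []
        spec1 = FitSpec(
            free=fit.spec.free,
            bounds=fit.spec.bounds,
            n_starts=1,
            maxiter=fit.spec.maxiter,
            tol=fit.spec.tol,
            seed=fit.spec.seed,
        )
        for b in range(n_bootstrap):
            resampled = table.sample(
                n=len(table), replace=True, random_state=int(rng.integers(2**31))
            )
            refit = fit_model(resampled, spec1, evaluator)
            boot.append([refit.estimates[n] for n in names])
        boot = np.asarray(boot)
        draws = boot[rng.integers(0, n_bootstrap, size=n_draws)]

    return pd.DataFrame(draws, columns=names)
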