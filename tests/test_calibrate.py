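"""Poisson likelihood, model fitting, LRT and uncertainty machinery."""

import numpy as np
import pandas as pd
import pytest

from msceoac import (
    FitSpec,
    HazardEvaluator,
    fit_model,
    likelihood_ratio_test,
    parameter_uncertainty,
    poisson_loglik,
    synth_incidence_table,
)
from msceoac.errors import InputError


class _StubCurve:
    def __init__(self, h):
        self.h = h

    def hazard_at(self, age):
        return np.full(np.shape(age), self.h)


class _StubEvaluator:
    """Fixed-hazard evaluator for checking the likelihood formula."""

    def __init__(self, h):
        self.h = h

    def curve(self, sex, cohort, overrides=None):
        return _StubCurve(self.h)


def small_table(cases, py=1000.0):
    return pd.DataFrame(
        {
            "sex": "M",
            "cohort": 1950,
            "age_low": [60.0],
            "age_high": [65.0],
            "cases": [cases],
            "person_years": [py],
        }
    )


class TestPoissonLoglik:
    def test_empty_model_and_data(self):
        assert poisson_loglik({}, small_table(0), _StubEvaluator(0.0)) == 0.0

    def test_direct_formula(self):
        # lambda = 1000 * 0.002 = 2; 2 ln2 - 2 - ln 2! = -1.3069
        ll = poisson_loglik({}, small_table(2), _StubEvaluator(0.002))
        assert np.isclose(ll, 2 * np.log(2) - 2 - np.log(2), atol=1e-4)

    def test_zero_rate_with_cases_guarded(self):
        ll = poisson_loglik({}, small_table(3), _StubEvaluator(0.0))
        assert ll <= -1e9

    def test_truth_beats_perturbations(self, cfg, evaluator, truth):
        table = synth_incidence_table(cfg, py_per_stratum=1e6, seed=3)
        ll_truth = poisson_loglik(truth, table, evaluator)
        rng = np.random.default_rng(17)
        wins = 0
        for _ in range(20):
            perturbed = {
                k: v * (1.0 + rng.uniform(-0.1, 0.1))
                for k, v in truth.items()
            }
            wins += ll_truth >= poisson_loglik(perturbed, table, evaluator)
        assert wins >= 19


class TestFitModel:
    def test_zero_onset_fits_at_lower_bound(self, cfg):
        zero_cfg = cfg.updated({"onset": {"nu0": {"M": 0.0, "F": 0.0}}})
        ev = HazardEvaluator(zero_cfg)
        table = synth_incidence_table(zero_cfg, py_per_stratum=1e6, seed=1,
                                      sexes=["M"], cohorts=[1950])
        assert table["cases"].sum() == 0
        fit = fit_model(table, FitSpec.from_config(cfg, ["nu0_M"], n_starts=1), ev)
        lo = fit.spec.bound("nu0_M")[0]
        assert fit.estimates["nu0_M"] <= lo * (1 + 1e-6)
        assert "nu0_M" in fit.at_bound

    def test_refit_same_seed_is_bit_identical(self, cfg, evaluator):
        table = synth_incidence_table(cfg, py_per_stratum=1e6, seed=5,
                                      sexes=["M"], cohorts=[1950])
        spec = FitSpec.from_config(cfg, ["nu0_M", "mu2"], n_starts=2, seed=9)
        fit1 = fit_model(table, spec, evaluator)
        fit2 = fit_model(table, spec, evaluator)
        assert fit1.estimates == fit2.estimates
        assert fit1.loglik == fit2.loglik

    def test_nested_fit_never_decreases_loglik(self, cfg, evaluator):
        table = synth_incidence_table(cfg, py_per_stratum=1e6, seed=6)
        null = fit_model(table, FitSpec.from_config(cfg, ["nu0"], n_starts=1), evaluator)
        alt = fit_model(
            table, FitSpec.from_config(cfg, ["nu0_M", "nu0_F"], n_starts=1), evaluator
        )
        assert alt.loglik >= null.loglik - 1e-6

    def test_empty_table_rejected(self, cfg, evaluator):
        with pytest.raises(InputError):
            fit_model(pd.DataFrame(), FitSpec.from_config(cfg, ["nu0"]), evaluator)


class TestLikelihoodRatioTest:
    def _fake_fit(self, loglik, n_free, cfg):
        from msceoac.calibrate import FitResult

        return FitResult(
            estimates={}, loglik=loglik, n_free=n_free,
            spec=FitSpec.from_config(cfg, ["nu0"]), status="converged",
            n_iter=0, n_evals=0,
        )

    def test_identical_loglik_gives_p_one(self, cfg):
        stat, df, p = likelihood_ratio_test(
            self._fake_fit(-10.0, 1, cfg), self._fake_fit(-10.0, 2, cfg)
        )
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_chi_square_quantile_identity(self, cfg):
        stat, df, p = likelihood_ratio_test(
            self._fake_fit(-10.0, 1, cfg), self._fake_fit(-10.0 + 3.841 / 2, 2, cfg)
        )
        assert np.isclose(p, 0.05, atol=5e-4)

    def test_non_nested_rejected(self, cfg):
        with pytest.raises(InputError):
            likelihood_ratio_test(
                self._fake_fit(-10.0, 2, cfg), self._fake_fit(-9.0, 2, cfg)
            )


@pytest.fixture(scope="module")
def fit(cfg, evaluator):
    table = synth_incidence_table(cfg, py_per_stratum=1e6, seed=8,
                                  sexes=["M"], cohorts=[1950])
    return fit_model(
        table, FitSpec.from_config(cfg, ["nu0_M"], n_starts=1), evaluator
    )


class TestParameterUncertainty:
    def test_same_seed_identical_draws(self, fit):
        d1 = parameter_uncertainty(fit, n_draws=150, seed=4)
        d2 = parameter_uncertainty(fit, n_draws=150, seed=4)
        pd.testing.assert_frame_equal(d1, d2)

    def test_draws_centre_on_estimate(self, fit):
        draws = parameter_uncertainty(fit, n_draws=400, seed=4)
        est = fit.estimates["nu0_M"]
        assert abs(draws["nu0_M"].mean() - est) < 0.2 * est
        assert fit.covariance_source == "observed_information"

    def test_interval_covers_truth_in_most_replicates(self, cfg, truth):
        """Nominal 95% intervals for nu0 cover truth in >= 90% of replicate
        fits at reduced size."""
        covered = 0
        n_rep = 100
        evaluator = HazardEvaluator(cfg)
        for rep in range(n_rep):
            table = synth_incidence_table(cfg, py_per_stratum=3e5, seed=1000 + rep,
                                          sexes=["M"], cohorts=[1950])
            fit = fit_model(
                table, FitSpec.from_config(cfg, ["nu0_M"], n_starts=1), evaluator
            )
            draws = parameter_uncertainty(fit, n_draws=300, seed=rep)
            lo, hi = np.quantile(draws["nu0_M"], [0.025, 0.975])
            covered += lo <= truth["nu0_M"] <= hi
        assert covered >= 90
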