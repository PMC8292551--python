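"""Backward survival system, segment marginalisation and hazard mixing."""

import numpy as np
import pytest

from msceoac import (
    BeSegmentModel,
    BiologicalParams,
    be_survival,
    incidence_per_100k,
    population_hazard,
    solve_backward_system,
)
from msceoac.hazard import BeSurvival, HazardCurve
from msceoac.errors import InputError
from msceoac.onset import BeOnsetModel, GerdModel
from msceoac.reference import riccati_sm

TAU = np.linspace(0.0, 20.0, 201)


def params(**kw):
    base = dict(mu0=1e-4, mu1=1e-4, alphaP=10.0, betaP=9.9, mu2=1e-5,
                alphaM=10.0, betaM=9.5, rho=0.02)
    base.update(kw)
    return BiologicalParams(**base)


def flat_gerd(rr=1.0):
    return GerdModel.from_logistic(p_max=0.0, k=0.1, t0=40.0, rr=rr)


class TestBackwardSystem:
    def test_no_detection_channel_survival_certain(self):
        sol = solve_backward_system(params(rho=0.0), TAU)
        for s in (sol.S_M, sol.S_P, sol.S_0):
            assert np.allclose(s, 1.0, atol=1e-8)

    def test_pure_detection_exponential(self):
        sol = solve_backward_system(params(alphaM=0.0, betaM=0.0, rho=0.5), np.linspace(0, 2, 21))
        assert np.isclose(sol.S_M[-1], np.exp(-1.0), atol=1e-8)

    @pytest.mark.parametrize("tau_target", [5.0, 10.0])
    def test_sm_matches_riccati_closed_form(self, tau_target):
        p = params()
        grid = np.linspace(0.0, tau_target, int(tau_target * 10) + 1)
        sol = solve_backward_system(p, grid)
        assert np.max(np.abs(sol.S_M - riccati_sm(p, grid))) < 1e-6

    def test_invariants_hold(self):
        sol = solve_backward_system(params(), TAU)
        for s in (sol.S_M, sol.S_P, sol.S_1, sol.S_0):
            assert s[0] == 1.0
            assert np.all(s >= 0.0) and np.all(s <= 1.0)
            assert np.all(np.diff(s) <= 1e-12)
        assert np.all(sol.dS0 <= 0.0)

    def test_rejects_bad_grid(self):
        with pytest.raises(InputError):
            solve_backward_system(params(), np.array([1.0, 2.0]))
        with pytest.raises(InputError):
            solve_backward_system(params(), np.array([0.0, 2.0, 1.0]))


class TestBeSurvival:
    def test_trivial_when_single_cell_survival_one(self):
        sol = solve_backward_system(params(rho=0.0), TAU)
        bs = be_survival(sol, BeSegmentModel())
        assert np.allclose(bs.s, 1.0, atol=1e-8)

    def test_single_cell_identity(self):
        # near-degenerate length law concentrated at L with N(L) = 1
        sol = solve_backward_system(params(rho=0.5, mu0=0.3, mu1=0.5, mu2=1e-3), TAU)
        seg = BeSegmentModel(beta_a=4000.0, beta_b=4000.0, length_max=2.0, cells_per_cm=1.0)
        bs = be_survival(sol, seg)
        assert np.allclose(bs.s, sol.S_0, rtol=1e-4)

    def test_matches_monte_carlo_marginalisation(self):
        # synthetic S_0(tau) = exp(-0.001 tau) against 1e6 sampled lengths
        tau = np.linspace(0.0, 10.0, 101)
        s0 = np.exp(-0.001 * tau)
        sol = solve_backward_system(params(), tau)
        object.__setattr__(sol, "S_0", s0)
        object.__setattr__(sol, "dS0", -0.001 * s0)
        seg = BeSegmentModel(beta_a=2, beta_b=6, length_max=10, cells_per_cm=100)
        bs = be_survival(sol, seg)
        rng = np.random.default_rng(2024)
        n_cells = 100.0 * rng.beta(2, 6, size=1_000_000) * 10.0
        samples = s0[50] ** n_cells
        mc, se = samples.mean(), samples.std() / 1000.0
        assert abs(bs.s[50] - mc) < 3 * se


class TestPopulationHazard:
    def grid(self):
        return np.linspace(0.0, 80.0, 801)

    def onset(self, nu0, rr=1.0):
        return BeOnsetModel(nu0=nu0, gerd=flat_gerd(rr))

    def be_surv_from(self, p):
        return be_survival(solve_backward_system(p, self.grid()), BeSegmentModel())

    def test_zero_onset_gives_zero_hazard(self):
        bs = self.be_surv_from(params(rho=0.5, mu0=0.1, mu1=0.1))
        curve = population_hazard(bs, self.onset(0.0), self.grid())
        assert np.allclose(curve.h_oac, 0.0)
        assert np.allclose(curve.p_be_cf, 0.0)
        assert np.allclose(curve.s_pop, 1.0)

    def test_no_progression_prevalence_is_cumulative_onset(self):
        grid = self.grid()
        bs = BeSurvival(tau_grid=grid, s=np.ones_like(grid), ds=np.zeros_like(grid))
        onset = self.onset(0.001)
        curve = population_hazard(bs, onset, grid)
        assert np.allclose(curve.h_oac, 0.0)
        expected = 1.0 - np.exp(-onset.cumulative_onset(grid))
        assert np.allclose(curve.p_be_cf, expected, atol=1e-6)

    def test_hazard_monotone_in_driver_rates(self):
        # three-point ladders in nu0, mu2 and rho
        grid = self.grid()
        base = params(rho=0.05, mu0=5e-3, mu1=5e-3, mu2=1e-4, alphaP=2.0, betaP=1.9,
                      alphaM=3.0, betaM=2.5)
        for name, values in [("nu0", [1e-4, 3e-4, 9e-4]),
                             ("mu2", [1e-4, 3e-4, 9e-4]),
                             ("rho", [0.02, 0.05, 0.1])]:
            curves = []
            for v in values:
                p = base if name == "nu0" else base.replace(**{name: v})
                nu0 = v if name == "nu0" else 3e-4
                curves.append(population_hazard(self.be_surv_from(p), self.onset(nu0), grid))
            for lo, hi in zip(curves[:-1], curves[1:]):
                assert np.all(hi.h_oac[1:] >= lo.h_oac[1:] - 1e-15), name
                assert np.all(lo.h_oac >= 0.0)

    def test_grid_mismatch_rejected(self):
        bs = self.be_surv_from(params())
        with pytest.raises(InputError):
            population_hazard(bs, self.onset(1e-4), np.linspace(0, 80, 401))


def test_incidence_per_100k_units():
    grid = np.array([0.0, 1.0, 2.0])
    curve = HazardCurve(age_grid=grid, h_oac=np.array([0.0, 1e-5, 2e-5]),
                        s_pop=np.ones(3), p_be_cf=np.zeros(3))
    assert np.allclose(incidence_per_100k(curve), [0.0, 1.0, 2.0])
    assert np.allclose(curve.incidence_per_100k, incidence_per_100k(curve))


def test_hazard_curve_serialises_to_csv_columns(male_curve, tmp_path):
    frame = male_curve.to_frame()
    expected = ["age", "hazard", "survival", "be_prevalence_cancer_free",
                "incidence_per_100k", "sex", "cohort", "subgroup"]
    assert list(frame.columns) == expected
    path = tmp_path / "curve.csv"
    frame.to_csv(path, index=False)
    assert path.exists()
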