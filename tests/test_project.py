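"""Census projection arithmetic, intervals, progression and sweeps."""

import numpy as np
import pandas as pd
import pytest

from msceoac import (
    attributable_fraction,
    be_carrier_count,
    expected_cases,
    make_census_table,
    prediction_interval,
    progression_rate,
    sweep_scenarios,
)
from msceoac.errors import InputError
from msceoac.hazard import HazardCurve


def flat_curve(h, p_be=0.0, max_age=100.0):
    grid = np.linspace(0.0, max_age, int(max_age) + 1)
    return HazardCurve(
        age_grid=grid,
        h_oac=np.full_like(grid, h),
        s_pop=np.ones_like(grid),
        p_be_cf=np.full_like(grid, p_be),
    )


def census_rows(rows):
    return pd.DataFrame(rows, columns=["year", "sex", "age", "person_years"])


class TestExpectedCases:
    def test_single_stratum_hand_sum(self):
        census = census_rows([(2010, "M", 60, 100000.0)])
        hazards = {("M", 1950): flat_curve(1e-4)}
        pred = expected_cases(hazards, census, 2010, (40, 90))
        assert np.isclose(pred.total, 10.0, atol=1e-12)

    def test_two_strata_hand_sum(self):
        census = census_rows([(2010, "M", 60, 50000.0), (2010, "F", 70, 200000.0)])
        hazards = {("M", 1950): flat_curve(2e-4), ("F", 1940): flat_curve(5e-5)}
        pred = expected_cases(hazards, census, 2010, (40, 90))
        assert np.isclose(pred.total, 20.0, atol=1e-12)

    def test_matches_row_by_row_oracle(self, cfg, evaluator):
        census = make_census_table(2010, total_py=5e7)
        pred = expected_cases(evaluator, census, 2010, (40, 90))
        # independent row-by-row sum
        total = 0.0
        known = sorted(cfg.cohort_multipliers)
        for _, row in census.iterrows():
            if not 40 <= row["age"] <= 90:
                continue
            cohort = int(np.floor((2010 - row["age"]) / 10) * 10)
            cohort = min(known, key=lambda c: abs(c - cohort))
            curve = evaluator.curve(row["sex"], cohort)
            total += row["person_years"] * float(curve.hazard_at(row["age"] + 0.5))
        assert abs(pred.total - total) < 1e-9 * total

    def test_linear_in_person_years(self, evaluator):
        census = make_census_table(2010, total_py=1e7)
        doubled = census.copy()
        doubled["person_years"] *= 2.0
        a = expected_cases(evaluator, census, 2010, (40, 90)).total
        b = expected_cases(evaluator, doubled, 2010, (40, 90)).total
        assert abs(b - 2.0 * a) < 1e-9 * b

    def test_missing_year_rejected(self, evaluator):
        census = make_census_table(2010, total_py=1e6)
        with pytest.raises(InputError, match="year"):
            expected_cases(evaluator, census, 1999, (40, 90))


class TestPredictionInterval:
    def test_identical_draws_collapse_to_point(self, cfg, evaluator):
        census = make_census_table(2010, total_py=1e6)
        point = expected_cases(
            evaluator, census, 2010, (40, 90),
            overrides={"nu0_M": cfg.nu0("M")},
        ).total
        draws = pd.DataFrame({"nu0_M": [cfg.nu0("M")] * 120})
        lo, hi = prediction_interval(evaluator, census, 2010, draws, (40, 90))
        assert lo == hi == pytest.approx(point, rel=1e-12)

    def test_permutation_invariance(self, cfg, evaluator):
        census = make_census_table(2010, total_py=1e6)
        rng = np.random.default_rng(0)
        values = cfg.nu0("M") * np.exp(rng.normal(0, 0.05, size=120))
        draws = pd.DataFrame({"nu0_M": values})
        shuffled = draws.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert prediction_interval(evaluator, census, 2010, draws, (40, 90)) == \
            prediction_interval(evaluator, census, 2010, shuffled, (40, 90))

    def test_too_few_draws_rejected(self, evaluator):
        census = make_census_table(2010, total_py=1e6)
        with pytest.raises(InputError):
            prediction_interval(evaluator, census, 2010,
                                pd.DataFrame({"nu0_M": [1e-4] * 50}), (40, 90))


class TestBeCarriers:
    def test_zero_prevalence(self):
        census = census_rows([(2010, "M", 60, 1e6)])
        count, frac = be_carrier_count({("M", 1950): flat_curve(0.0)}, census, 2010, (40, 90))
        assert count == 0.0 and frac == 0.0

    def test_uniform_prevalence_arithmetic(self):
        census = census_rows([(2010, "M", 60, 1e6)])
        hazards = {("M", 1950): flat_curve(0.0, p_be=0.016)}
        count, frac = be_carrier_count(hazards, census, 2010, (40, 90))
        assert np.isclose(count, 16000.0) and np.isclose(frac, 0.016)


class TestProgression:
    def test_zero_hazard(self):
        assert progression_rate(flat_curve(0.0, p_be=0.01), 60.0) == 0.0

    def test_saturation_limit(self, cfg):
        # nu0 x1000 drives p_be_cf -> ~1 so progression ~ h_OAC
        from msceoac import HazardEvaluator

        sat = cfg.updated({"onset": {"nu0": {"M": 0.26, "F": 0.065}}})
        curve = HazardEvaluator(sat).curve("M", 1950)
        rate = progression_rate(curve, 70.0)
        assert abs(rate - curve.hazard_at(70.0)) / rate < 0.01

    def test_identity_with_prevalence(self, male_curve):
        for age in (50.0, 60.0, 70.0):
            assert np.isclose(
                progression_rate(male_curve, age) * male_curve.prevalence_at(age),
                male_curve.hazard_at(age),
                rtol=1e-12,
            )

    def test_undefined_below_floor(self):
        with pytest.raises(InputError, match="floor"):
            progression_rate(flat_curve(1e-5, p_be=0.0), 60.0)


class TestAttributableFraction:
    @pytest.mark.parametrize(
        "pred,obs,expected", [(9400.0, 9400.0, 1.0), (0.0, 9400.0, 0.0), (9970.0, 9400.0, 1.0)]
    )
    def test_examples(self, pred, obs, expected):
        out = attributable_fraction(pred, obs)
        assert out["fraction"] == pytest.approx(expected)
        assert 0.0 <= out["fraction"] <= 1.0
        assert out["unexplained"] == pytest.approx(1.0 - expected)

    def test_overprediction_reports_excess(self):
        out = attributable_fraction(9970.0, 9400.0)
        assert out["excess"] == pytest.approx(9970.0 / 9400.0 - 1.0)

    def test_invalid_observed(self):
        with pytest.raises(InputError):
            attributable_fraction(10.0, 0.0)


@pytest.fixture(scope="module")
def sweep_census():
    return make_census_table(2010, total_py=1e7)


class TestSweep:
    def test_base_grid_matches_pipeline(self, cfg, evaluator, sweep_census):
        census = sweep_census
        table = sweep_scenarios(cfg, {"rr": [5.0]}, census, 2010)
        assert len(table) == 1
        base = expected_cases(evaluator, census, 2010, cfg.age_range).total
        assert table["expected_cases"].iloc[0] == pytest.approx(base, rel=1e-12)

    def test_rr_grid_monotone_prevalence(self, cfg, sweep_census):
        census = sweep_census
        table = sweep_scenarios(cfg, {"rr": [2.0, 6.0]}, census, 2010)
        prev = table.sort_values("rr")["gerd_be_prevalence_M"].to_numpy()
        assert prev[1] >= prev[0]

    def test_grid_shape_and_reproducibility(self, cfg, sweep_census):
        census = sweep_census
        grid = {"rr": [2.0, 4.0, 6.0], "gerd_scale": [0.8, 1.2]}
        t1 = sweep_scenarios(cfg, grid, census, 2010)
        assert len(t1) == 6
        single = sweep_scenarios(cfg, {"rr": [4.0], "gerd_scale": [1.2]}, census, 2010)
        row = t1[(t1["rr"] == 4.0) & (t1["gerd_scale"] == 1.2)].reset_index(drop=True)
        pd.testing.assert_frame_equal(row, single)

    def test_invalid_scenario_named(self, cfg, sweep_census):
        census = sweep_census
        with pytest.raises(InputError, match="gerd_scale=10"):
            sweep_scenarios(cfg, {"gerd_scale": [10.0]}, census, 2010)
        with pytest.raises(InputError, match="magnetism"):
            sweep_scenarios(cfg, {"magnetism": [1.0]}, census, 2010)
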