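"""Sibling-history and household-death direct estimation."""

import numpy as np
import pandas as pd
import pytest

from crvsddm.survey import (
    HouseholdSurveyModel,
    SiblingSurveyModel,
    adult_grid,
    direct_35q15,
    household_rates,
    impute_sibling_dates,
    screen_survey_weights,
    sibling_exposure,
)


def _sib_row(**kw):
    base = dict(respondent_id=0, weight=1.0, sib_sex="female", alive=True,
                current_age=np.nan, age_at_death=np.nan,
                years_since_death=np.nan, birth_date=np.nan,
                death_date=np.nan, interview_date=2019.0)
    base.update(kw)
    return base


def single_year_exposure_oracle(df, period, sex):
    """Independent exposure oracle: loop records x single years of age."""
    p0, p1 = period
    py = np.zeros(7)
    for _, r in df[df["sib_sex"] == sex].iterrows():
        end = r["death_date"] if not r["alive"] else r["interview_date"]
        for age in range(15, 50):
            lo = max(r["birth_date"] + age, p0)
            hi = min(r["birth_date"] + age + 1, end, p1)
            if hi > lo:
                py[(age - 15) // 5] += r["weight"] * (hi - lo)
    return py


class TestImputation:
    def test_dead_sibling_midpoint_convention(self):
        df = pd.DataFrame([_sib_row(alive=False, age_at_death=30,
                                    years_since_death=4)])
        out, n_bad = impute_sibling_dates(df)
        assert n_bad == 0
        assert out.loc[0, "death_date"] == pytest.approx(2014.5)
        assert out.loc[0, "birth_date"] == pytest.approx(1984.0)

    def test_living_sibling_midpoint_convention(self):
        df = pd.DataFrame([_sib_row(current_age=25)])
        out, _ = impute_sibling_dates(df)
        assert out.loc[0, "birth_date"] == pytest.approx(1993.5)

    def test_explicit_dates_never_overwritten(self):
        df = pd.DataFrame([_sib_row(alive=False, age_at_death=30,
                                    years_since_death=4, birth_date=1980.25,
                                    death_date=2010.75)])
        out, _ = impute_sibling_dates(df)
        assert out.loc[0, "birth_date"] == 1980.25
        assert out.loc[0, "death_date"] == 2010.75

    def test_unusable_dead_record_dropped_and_counted(self):
        df = pd.DataFrame([
            _sib_row(alive=False),               # nothing to impute from
            _sib_row(current_age=30),
        ])
        out, n_bad = impute_sibling_dates(df)
        assert n_bad == 1 and len(out) == 1


class TestSiblingExposure:
    def test_survivor_contributes_full_period_in_one_cell(self):
        df = pd.DataFrame([_sib_row(birth_date=1990.0,
                                    interview_date=2019.5)])
        exp = sibling_exposure(df, (2010.0, 2015.0), "female")
        assert exp.person_years.sum() == pytest.approx(5.0)
        assert exp.person_years[adult_grid().index_of(20)] == pytest.approx(5.0)
        assert exp.deaths.sum() == 0

    def test_death_truncates_exposure_and_counts_once(self):
        df = pd.DataFrame([_sib_row(alive=False, birth_date=1990.0,
                                    death_date=2012.0)])
        exp = sibling_exposure(df, (2010.0, 2015.0), "female")
        assert exp.person_years.sum() == pytest.approx(2.0)
        assert exp.deaths[adult_grid().index_of(20)] == 1.0

    def test_empty_records_all_zero(self):
        df = pd.DataFrame([_sib_row()]).iloc[:0]
        exp = sibling_exposure(df, (2010.0, 2015.0), "female")
        assert exp.person_years.sum() == 0 and exp.deaths.sum() == 0

    def test_inverted_period_errors(self):
        df = pd.DataFrame([_sib_row(birth_date=1990.0)])
        with pytest.raises(ValueError):
            sibling_exposure(df, (2015.0, 2010.0), "female")

    def test_matches_single_year_oracle_on_random_records(self,
                                                          adult_lifetable):
        from crvsddm.simulate import make_sibling_survey

        df = make_sibling_survey(300, None, adult_lifetable, 2019.0, seed=21)
        df, _ = impute_sibling_dates(df)
        period = (2005.0, 2019.0)
        for sex in ("female", "male"):
            exp = sibling_exposure(df, period, sex)
            oracle = single_year_exposure_oracle(df, period, sex)
            np.testing.assert_allclose(exp.person_years, oracle, rtol=1e-6)

    def test_deaths_only_in_their_own_cell(self, adult_lifetable):
        from crvsddm.simulate import make_sibling_survey

        df = make_sibling_survey(400, None, adult_lifetable, 2019.0, seed=22)
        df, _ = impute_sibling_dates(df)
        p0, p1 = 2009.0, 2019.0
        exp = sibling_exposure(df, (p0, p1), "female")
        sub = df[(df.sib_sex == "female") & (~df.alive)]
        age_d = sub.death_date - sub.birth_date
        in_cell = ((sub.death_date >= p0) & (sub.death_date < p1)
                   & (age_d >= 15) & (age_d < 50))
        assert exp.deaths.sum() == in_cell.sum()


class TestDirect35q15:
    def test_zero_deaths_zero_probability(self):
        df = pd.DataFrame([
            _sib_row(respondent_id=i, birth_date=1990.0 - 5 * j,
                     interview_date=2019.5)
            for i in range(10) for j in range(7)
        ])
        exp = sibling_exposure(df, (2005.0, 2010.0), "female")
        res = direct_35q15(exp, n_boot=10, seed=0)
        assert res.q3515 == 0.0

    def test_weight_rescaling_invariance(self, adult_lifetable):
        from crvsddm.simulate import make_sibling_survey

        df = make_sibling_survey(500, None, adult_lifetable, 2019.0, seed=23)
        df, _ = impute_sibling_dates(df)
        exp1 = sibling_exposure(df, (2009.0, 2019.0), "female")
        df2 = df.assign(weight=df.weight * 17.3)
        exp2 = sibling_exposure(df2, (2009.0, 2019.0), "female")
        r1 = direct_35q15(exp1, n_boot=0)
        r2 = direct_35q15(exp2, n_boot=0)
        assert r1.q3515 == pytest.approx(r2.q3515, rel=1e-12)

    def test_record_order_invariance(self, adult_lifetable):
        from crvsddm.simulate import make_sibling_survey

        df = make_sibling_survey(500, None, adult_lifetable, 2019.0, seed=24)
        df, _ = impute_sibling_dates(df)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1 = direct_35q15(sibling_exposure(df, (2009.0, 2019.0), "male"),
                          n_boot=0)
        r2 = direct_35q15(sibling_exposure(shuffled, (2009.0, 2019.0), "male"),
                          n_boot=0)
        assert r1.q3515 == pytest.approx(r2.q3515, rel=1e-12)

    def test_zero_exposure_cell_reported(self):
        df = pd.DataFrame([_sib_row(birth_date=1999.0,
                                    interview_date=2019.5)])
        exp = sibling_exposure(df, (2015.0, 2019.0), "female")
        with pytest.raises(ValueError, match="zero exposure"):
            direct_35q15(exp)


class TestWeightScreening:
    @pytest.mark.parametrize("frac, usable", [(0.96, False), (0.0, True),
                                              (0.5, True), (0.51, False)])
    def test_threshold_rule(self, frac, usable):
        n = 1000
        w = np.ones(n)
        w[: int(frac * n)] = np.nan
        verdict = screen_survey_weights(pd.DataFrame({"weight": w}))
        assert verdict.usable is usable
        assert verdict.missing_fraction == pytest.approx(frac, abs=1e-9)

    def test_model_refuses_unusable_weights(self, adult_lifetable):
        from crvsddm.simulate import make_sibling_survey

        df = make_sibling_survey(300, None, adult_lifetable, 2019.0, seed=25,
                                 weight_missing_frac=0.96)
        model = SiblingSurveyModel(df)
        with pytest.raises(ValueError, match="unusable"):
            model.fit((2009.0, 2019.0), n_boot=0)


class TestHouseholdRates:
    def test_direct_count_example(self):
        # 1,000 members aged 20-24 throughout a 5-year window, 10 deaths
        rows = []
        for i in range(1000):
            died = i < 10
            rows.append(dict(household_id=i, weight=1.0, sex="female",
                             age=22, died=died,
                             death_date=2016.0 + (i % 5) if died else np.nan,
                             survey_date=2019.0))
        df = pd.DataFrame(rows)
        # place deaths inside the window and keep everyone in one cell
        df.loc[df.died, "death_date"] = np.linspace(2014.2, 2018.8, 10)
        res = household_rates(df, 2019.0, 5.0)
        i20 = res.grid.index_of(20)
        # all deaths land in the 20-24 cell; aggregate rate ~ 10/5000
        assert res.deaths["female"][i20] == 10
        assert res.deaths["female"].sum() == 10
        py = res.person_years["female"].sum()
        M = res.deaths["female"].sum() / py
        assert M == pytest.approx(0.002, rel=0.02)

    def test_zero_deaths_zero_rates(self):
        df = pd.DataFrame([dict(household_id=0, weight=1.0, sex="male",
                                age=30, died=False, death_date=np.nan,
                                survey_date=2019.0)])
        res = household_rates(df, 2019.0, 5.0)
        assert res.deaths["male"].sum() == 0
        with pytest.raises(ValueError):
            res.q3515("male")  # zero exposure outside the observed cell

    def test_window_must_be_positive(self):
        df = pd.DataFrame([dict(household_id=0, weight=1.0, sex="male",
                                age=30, died=False, death_date=np.nan,
                                survey_date=2019.0)])
        with pytest.raises(ValueError):
            household_rates(df, 2019.0, 0.0)

    def test_mid_period_label(self):
        df = pd.DataFrame([dict(household_id=0, weight=1.0, sex="male",
                                age=30, died=False, death_date=np.nan,
                                survey_date=2018.0)])
        res = HouseholdSurveyModel(df).fit(window_years=5.0)
        assert res.mid_period == pytest.approx(2015.5)

    def test_rate_recovery_from_generator(self, grid):
        # power-sized roster so the thinnest adult cell still holds
        # a few hundred expected deaths
        from crvsddm import RateSchedule
        from crvsddm.simulate import ScenarioTruth, make_household_survey

        truth = ScenarioTruth()
        M = truth.hazard(grid.starts + 2.5)
        sched = RateSchedule(grid=grid, sex="female", M=M)
        df = make_household_survey(250_000, sched, 2019.0, 5.0, seed=26,
                                   age_range=(10.0, 50.0))
        res = household_rates(df, 2019.0, 5.0, grid=grid)
        lo, hi = grid.index_of(15), grid.index_of(45)
        for sex in res.deaths:
            est = res.deaths[sex][lo:hi + 1] / res.person_years[sex][lo:hi + 1]
            rel = est / M[lo:hi + 1] - 1.0
            assert np.max(np.abs(rel)) < 0.15
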