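import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from atlas_smooth.standardisation import (
    age_group,
    attach_expected_deaths,
    build_strata,
    expected_cases,
    period_person_time,
    stratum_levels,
    SurvivalTable,
)


class TestExpectedCases:
    def test_worked_example(self):
        y = [[2, 0], [0, 2]]
        n = [[100, 100], [100, 100]]
        data = expected_cases(y, n, area_ids=["a", "b"])
        assert np.allclose(data.E, [2.0, 2.0])
        assert np.allclose(data.y, [2, 2])

    def test_identical_age_structure_gives_proportional_E(self):
        n = np.array([[100.0, 200.0], [200.0, 400.0], [50.0, 100.0]])
        y = np.array([[5, 8], [9, 17], [3, 4]])
        data = expected_cases(y, n)
        totals = n.sum(axis=1)
        assert np.allclose(data.E / data.E[0], totals / totals[0])

    @settings(max_examples=50, deadline=None)
    @given(
        y=arrays(np.int64, (4, 3), elements=st.integers(0, 50)),
        n=arrays(np.int64, (4, 3), elements=st.integers(1, 10_000)),
    )
    def test_internal_standardisation_identity(self, y, n):
        data = expected_cases(y, n)
        assert data.E.sum() == pytest.approx(float(y.sum()), abs=1e-9)

    def test_zero_population_with_cases_rejected(self):
        with pytest.raises(ValueError, match="zero national population"):
            expected_cases([[1, 0]], [[0, 10]])

    def test_long_frame_input(self):
        cases = pd.DataFrame(
            {"area": ["a", "a", "b", "b"], "age_band": ["y", "o", "y", "o"],
             "count": [2, 0, 0, 2]}
        )
        pop = pd.DataFrame(
            {"area": ["a", "a", "b", "b"], "age_band": ["y", "o", "y", "o"],
             "count": [100, 100, 100, 100]}
        )
        data = expected_cases(cases, pop)
        assert np.allclose(data.E, [2.0, 2.0])


class TestBuildStrata:
    def test_age_cutpoints(self):
        assert age_group(54) == 0
        assert age_group(55) == 1
        assert age_group(64) == 1
        assert age_group(65) == 2
        assert age_group(74) == 2
        assert age_group(75) == 3
        assert age_group(89) == 3

    def test_sex_specific_model_has_no_sex_dimension(self):
        assert build_strata(60, sex="F") == "age55-64"

    def test_persons_model_crosses_sex(self):
        assert build_strata(60, sex="F", persons_model=True) == "age55-64|F"
        assert len(stratum_levels(persons_model=True)) == 8

    def test_site_crossing(self):
        label = build_strata(40, cancer_site="x", sites=("x", "y"))
        assert label == "age15-54|x"

    def test_age_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            age_group(90)
        with pytest.raises(ValueError, match="outside"):
            age_group(14)


def _patients(rows):
    return pd.DataFrame(rows, columns=["area", "stratum", "diag_time", "end_time", "event"])


class TestPeriodPersonTime:
    def test_death_mid_window(self):
        table = period_person_time(
            _patients([("a", "s", 2005.0, 2007.5, 1)]), min_diagnosis=2001.0
        )
        c = table.cells.set_index("followup_year")
        assert c.loc[1, "person_time"] == pytest.approx(0.0)
        assert c.loc[2, "person_time"] == pytest.approx(1.0)
        assert c.loc[3, "person_time"] == pytest.approx(0.5)
        assert c.loc[3, "deaths"] == 1
        assert c["deaths"].sum() == 1

    def test_late_diagnosis_contributes_fraction_of_first_year(self):
        table = period_person_time(_patients([("a", "s", 2014.9, 2015.0, 0)]))
        c = table.cells.set_index("followup_year")
        assert c.loc[1, "person_time"] == pytest.approx(0.1)
        assert c["person_time"].sum() == pytest.approx(0.1)

    def test_early_diagnosis_contributes_nothing(self):
        table = period_person_time(_patients([("a", "s", 2001.0, 2015.0, 0)]))
        assert table.cells["person_time"].sum() == pytest.approx(0.0)

    def test_death_before_diagnosis_rejected(self):
        with pytest.raises(ValueError, match="before diagnosis"):
            period_person_time(_patients([("a", "s", 2008.0, 2007.0, 1)]))

    def test_pre_cohort_diagnosis_rejected(self):
        with pytest.raises(ValueError, match="2001"):
            period_person_time(_patients([("a", "s", 1999.0, 2008.0, 0)]))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            period_person_time(_patients([("a", "s", 2006.0, 2010.0, 0)]),
                               window=(2010.0, 2010.0))

    def test_matches_daily_discretised_oracle(self):
        rng = np.random.default_rng(12)
        rows = []
        for i in range(40):
            diag = rng.uniform(2001.0, 2014.99)
            end = diag + rng.uniform(0.0, 12.0)
            rows.append(("a", "s", diag, end, int(rng.random() < 0.5)))
        table = period_person_time(_patients(rows))
        # brute-force per-day oracle
        day = 1.0 / 365.0
        oracle = 0.0
        for _, _, diag, end, _ in rows:
            ts = np.arange(diag, min(end, diag + 5.0), day)
            ts = ts[(ts >= 2006.0) & (ts < 2015.0)]
            oracle += ts.size * day
        assert table.cells["person_time"].sum() == pytest.approx(oracle, abs=len(rows) / 365.0)


class TestAttachExpectedDeaths:
    def test_scalar_rate(self):
        table = period_person_time(_patients([("a", "s", 2007.0, 2015.0, 0)]))
        out = attach_expected_deaths(table, 0.01)
        got = out.cells.set_index("followup_year")["expected_deaths"]
        assert got.loc[1] == pytest.approx(0.01)

    def test_zero_person_time_cell_gets_zero(self):
        table = period_person_time(_patients([("a", "s", 2014.5, 2015.0, 0)]))
        out = attach_expected_deaths(table, 0.05)
        c = out.cells.set_index("followup_year")
        assert c.loc[5, "expected_deaths"] == 0.0

    def test_year_varying_rates_sum_over_slices(self):
        # one follow-up year split across two calendar years with different rates
        table = period_person_time(_patients([("a", "s", 2007.5, 2015.0, 0)]))
        rates = {2007: 0.02, 2008: 0.04, 2009: 0.02, 2010: 0.02, 2011: 0.02,
                 2012: 0.02, 2013: 0.02, 2014: 0.02}
        out = attach_expected_deaths(table, rates)
        # follow-up year 1 spans 2007.5-2008.5: 0.5 yr at 0.02 + 0.5 yr at 0.04
        got = out.cells.set_index("followup_year")["expected_deaths"]
        assert got.loc[1] == pytest.approx(0.5 * 0.02 + 0.5 * 0.04)

    def test_missing_rate_rejected(self):
        table = period_person_time(_patients([("a", "s", 2007.0, 2015.0, 0)]))
        with pytest.raises(KeyError, match="no background rate"):
            attach_expected_deaths(table, {2007: 0.01})


class TestSurvivalTableInvariants:
    def test_deaths_without_person_time_rejected(self):
        cells = pd.DataFrame(
            [("a", "s", 1, 3, 0.0, 0.0)],
            columns=["area", "stratum", "followup_year", "deaths", "person_time",
                     "expected_deaths"],
        )
        with pytest.raises(ValueError, match="zero person-time"):
            SurvivalTable(cells)

    def test_followup_bounds(self):
        cells = pd.DataFrame(
            [("a", "s", 6, 0, 1.0, 0.0)],
            columns=["area", "stratum", "followup_year", "deaths", "person_time",
                     "expected_deaths"],
        )
        with pytest.raises(ValueError, match="1..5"):
            SurvivalTable(cells)

    def test_indicator_matrix_partition(self):
        table = period_person_time(
            _patients([("a", "s1", 2008.0, 2015.0, 0), ("a", "s2", 2009.0, 2015.0, 0)])
        )
        X = table.indicator_matrix()
        assert np.array_equal(X.sum(axis=1), np.ones(len(table.cells)))
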