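"""Panel assembly, calendar covariates and temperature imputation."""

import numpy as np
import pandas as pd
import pytest

from bathmort.panel import (
    HolidayCalendar,
    RegionPanel,
    count_prefecture_days,
    day_of_year_365,
    impute_temperature,
    read_panel,
    write_panel_tables,
)
from bathmort.simulate import make_holiday_calendar


def _panel_from_temps(dates, temps, region="A"):
    frame = pd.DataFrame(
        {
            "date": dates,
            "deaths": 0,
            "tmean": temps,
            "population": 1e6,
            "prop65": 0.2,
            "doy": day_of_year_365(dates),
            "dow": dates.dayofweek + 1,
            "year": dates.year,
            "is_holiday": False,
            "is_new_years_day": False,
            "is_new_years_eve": False,
            "is_coming_of_age_day": False,
        }
    )
    return RegionPanel(region, frame)


class TestCalendar:
    def test_feb29_shares_day_59_and_cycle_stays_365(self):
        dates = pd.date_range("1996-01-01", "1996-12-31", freq="D")
        doy = day_of_year_365(dates)
        assert doy.max() == 365
        feb28 = doy[dates.get_loc(pd.Timestamp("1996-02-28"))]
        feb29 = doy[dates.get_loc(pd.Timestamp("1996-02-29"))]
        mar01 = doy[dates.get_loc(pd.Timestamp("1996-03-01"))]
        assert feb28 == feb29 == 59
        assert mar01 == 60
        assert doy[-1] == 365

    def test_dow_convention_monday_one(self):
        # 2000-01-03 was a Monday
        dates = pd.date_range("2000-01-03", periods=7, freq="D")
        assert list(dates.dayofweek + 1) == [1, 2, 3, 4, 5, 6, 7]

    def test_new_years_eve_not_in_holiday_class(self):
        cal = make_holiday_calendar([2001])
        nye = pd.Timestamp("2001-12-31")
        assert nye in set(cal.dates_with_label("new_years_eve"))
        assert nye not in set(cal.holiday_dates)

    def test_coming_of_age_day_rule_change(self):
        cal = make_holiday_calendar([1999, 2000])
        coa = sorted(cal.dates_with_label("coming_of_age_day"))
        assert coa[0] == pd.Timestamp("1999-01-15")
        assert coa[1].dayofweek == 0 and 8 <= coa[1].day <= 14  # 2nd Monday

    def test_duplicate_holiday_dates_rejected(self):
        tab = pd.DataFrame(
            {"date": pd.to_datetime(["2001-01-01", "2001-01-01"]),
             "label": ["new_years_day", "holiday"]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            HolidayCalendar(tab)


class TestCountPrefectureDays:
    @pytest.mark.parametrize(
        "start,end,k,expected",
        [
            ("1995-01-01", "2020-12-31", 47, 446_359),
            ("2001-01-01", "2001-12-31", 1, 365),
            ("1996-01-01", "1996-12-31", 2, 732),
        ],
    )
    def test_known_counts(self, start, end, k, expected):
        assert count_prefecture_days(start, end, k) == expected

    def test_matches_brute_force_iteration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            start = pd.Timestamp("1980-01-01") + pd.Timedelta(days=int(rng.integers(0, 5000)))
            end = start + pd.Timedelta(days=int(rng.integers(0, 18000)))
            brute = len(pd.date_range(start, end, freq="D"))
            assert count_prefecture_days(start, end, 3) == brute * 3

    def test_reversed_range_rejected(self):
        with pytest.raises(ValueError):
            count_prefecture_days("2001-01-02", "2001-01-01", 1)


class TestImputation:
    def test_mean_of_prior_year_donors(self):
        dates = pd.date_range("1996-01-01", "2000-12-31", freq="D")
        temps = np.full(len(dates), 10.0)
        for year, val in zip(range(1996, 2000), [20.0, 21.0, 22.0, 23.0]):
            temps[dates.get_loc(pd.Timestamp(year, 7, 15))] = val
        temps[dates.get_loc(pd.Timestamp(2000, 7, 15))] = np.nan
        out = impute_temperature(_panel_from_temps(dates, temps))
        filled = out.data.loc[out.dates.get_loc(pd.Timestamp(2000, 7, 15)), "tmean"]
        assert filled == pytest.approx(21.5)

    def test_strictly_earlier_years_only_first_year_errors(self):
        dates = pd.date_range("1995-01-01", "1996-12-31", freq="D")
        temps = np.full(len(dates), 10.0)
        temps[dates.get_loc(pd.Timestamp("1995-03-01"))] = np.nan
        with pytest.raises(ValueError, match="1995-03-01"):
            impute_temperature(_panel_from_temps(dates, temps))

    def test_idempotent_and_preserves_observed(self):
        dates = pd.date_range("1999-01-01", "2001-12-31", freq="D")
        rng = np.random.default_rng(1)
        temps = rng.normal(15, 8, len(dates))
        temps[900] = np.nan
        once = impute_temperature(_panel_from_temps(dates, temps))
        twice = impute_temperature(once)
        np.testing.assert_array_equal(once.data["tmean"], twice.data["tmean"])
        mask = ~np.isnan(temps)
        np.testing.assert_array_equal(once.data["tmean"].to_numpy()[mask], temps[mask])

    def test_no_missing_returns_identical(self):
        dates = pd.date_range("1999-01-01", "1999-12-31", freq="D")
        p = _panel_from_temps(dates, np.full(len(dates), 5.0))
        assert impute_temperature(p) is p


class TestPanelInvariants:
    def test_date_gap_rejected_with_location(self):
        dates = pd.DatetimeIndex(
            list(pd.date_range("2000-01-01", "2000-01-10"))
            + list(pd.date_range("2000-01-12", "2000-01-20"))
        )
        with pytest.raises(ValueError, match="2000-01-10"):
            _panel_from_temps(dates, np.zeros(len(dates)))

    def test_roundtrip_write_read_lossless(self, small_sim, tmp_path):
        paths = write_panel_tables(small_sim.panels, small_sim.holidays, tmp_path)
        back = read_panel(
            paths["deaths"], paths["temperature"], paths["population"], paths["holidays"]
        )
        assert len(back) == len(small_sim.panels)
        for orig, rt in zip(small_sim.panels, back):
            assert rt.region_id == orig.region_id
            for col in ["deaths", "doy", "dow", "year", "is_holiday",
                        "is_new_years_day", "is_new_years_eve", "is_coming_of_age_day"]:
                np.testing.assert_array_equal(rt.data[col], orig.data[col])
            for col in ["tmean", "population", "prop65"]:
                np.testing.assert_allclose(rt.data[col], orig.data[col], rtol=0, atol=1e-9)

    def test_read_panel_errors_on_unimputable_missing_temperature(self, tmp_path):
        deaths = pd.DataFrame(
            {"region": "A", "date": ["1995-01-01", "1995-01-02"], "deaths": [1, 2]}
        )
        temps = pd.DataFrame(
            {"region": "A", "date": ["1995-01-01"], "tmean_c": [3.0]}
        )
        pops = pd.DataFrame(
            {"region": "A", "year": [1995], "population": [1e6], "prop65": [0.2]}
        )
        hol = HolidayCalendar(pd.DataFrame({"date": pd.to_datetime(["1995-01-01"]),
                                            "label": ["new_years_day"]}))
        with pytest.raises(ValueError, match="A.*1995-01-02"):
            read_panel(deaths, temps, pops, hol)

    def test_read_panel_rejects_duplicate_rows(self):
        deaths = pd.DataFrame(
            {"region": ["A", "A"], "date": ["1995-01-01", "1995-01-01"], "deaths": [1, 2]}
        )
        temps = pd.DataFrame({"region": "A", "date": ["1995-01-01"], "tmean_c": [3.0]})
        pops = pd.DataFrame({"region": "A", "year": [1995], "population": [1e6], "prop65": [0.2]})
        hol = HolidayCalendar(pd.DataFrame({"date": pd.to_datetime([]), "label": []}))
        with pytest.raises(ValueError, match="duplicate"):
            read_panel(deaths, temps, pops, hol)
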