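"""Daily region panels: reading, calendar covariates, temperature imputation.

The analytic unit is the *region-day*: one calendar day in one region, with a
death count, a daily mean outdoor temperature, the yearly population and the
yearly proportion of residents aged 65+, plus calendar covariates (day-of-year
on a 365-day cycle, day-of-week, holiday indicators).

Input tables are plain CSV:

- ``deaths.csv``:       region, date (ISO-8601), deaths
- ``temperature.csv``:  region, date, tmean_c  (empty cell = missing)
- ``population.csv``:   region, year, population, prop65
- ``holidays.csv``:     date, label

The labels ``new_years_day``, ``new_years_eve`` and ``coming_of_age_day`` are
recognised specially.  Any holiday row marks ``is_holiday`` except
``new_years_eve`` — December 31 is not a statutory holiday and is flagged only
through its own indicator (callers may merge it back into the holiday class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegionPanel",
    "HolidayCalendar",
    "day_of_year_365",
    "build_calendar",
    "read_panel",
    "impute_temperature",
    "count_prefecture_days",
    "write_panel_tables",
    "load_holidays",
]

#: Day-of-week convention: Monday=1 .. Sunday=7; Friday (5) is the reference
#: level for day-of-week contrasts.
DOW_REFERENCE = 5

_SPECIAL_LABELS = ("new_years_day", "new_years_eve", "coming_of_age_day")

_CALENDAR_COLS = [
    "doy",
    "dow",
    "year",
    "is_holiday",
    "is_new_years_day",
    "is_new_years_eve",
    "is_coming_of_age_day",
]


@dataclass(frozen=True)
class HolidayCalendar:
    """Holiday dates with labels; no duplicate dates allowed."""

    table: pd.DataFrame  # columns: date (datetime64), label (str)

    def __post_init__(self) -> None:
        tab = self.table
        if not {"date", "label"} <= set(tab.columns):
            raise ValueError("holiday table needs columns 'date' and 'label'")
        if tab["date"].duplicated().any():
            dups = tab.loc[tab["date"].duplicated(), "date"].dt.date.tolist()
            raise ValueError(f"duplicate holiday dates: {dups}")

    def dates_with_label(self, label: str) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.table.loc[self.table["label"] == label, "date"])

    @property
    def holiday_dates(self) -> pd.DatetimeIndex:
        """Statutory holidays: every row except New Year's Eve."""
        keep = self.table["label"] != "new_years_eve"
        return pd.DatetimeIndex(self.table.loc[keep, "date"])


@dataclass
class RegionPanel:
    """Aligned daily series for one region.

    ``data`` holds one row per consecutive calendar day with columns
    date, deaths, tmean, population, prop65, doy, dow, year, is_holiday,
    is_new_years_day, is_new_years_eve, is_coming_of_age_day.
    """

    region_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        dates = pd.DatetimeIndex(df["date"])
        if dates.duplicated().any():
            raise ValueError(f"region {self.region_id}: duplicate dates")
        diffs = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if (diffs != 1).any():
            i = int(np.argmax(diffs != 1))
            raise ValueError(
                f"region {self.region_id}: date gap between "
                f"{dates[i].date()} and {dates[i + 1].date()}"
            )
        if (df["deaths"].to_numpy() < 0).any():
            raise ValueError(f"region {self.region_id}: negative death counts")
        if (df["population"].to_numpy() <= 0).any():
            raise ValueError(f"region {self.region_id}: non-positive population")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["date"])

    def copy(self) -> "RegionPanel":
        return RegionPanel(self.region_id, self.data.copy())


def day_of_year_365(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year on a fixed 1..365 grid.

    February 29 shares day 59 with February 28, and every later day of a leap
    year is shifted down by one, so the cycle length is 365 in every year.
    """
    dates = pd.DatetimeIndex(dates)
    doy = dates.dayofyear.to_numpy().copy()
    leap = dates.is_leap_year
    after_feb28 = doy > 59  # Feb 29 has dayofyear 60 in leap years
    doy[leap & after_feb28] -= 1
    return doy


def build_calendar(dates: pd.DatetimeIndex, holidays: HolidayCalendar) -> pd.DataFrame:
    """Calendar covariates for a run of dates: doy, dow, year, holiday flags."""
    dates = pd.DatetimeIndex(dates)
    out = pd.DataFrame(
        {
            "doy": day_of_year_365(dates),
            "dow": dates.dayofweek.to_numpy() + 1,  # Monday=1 .. Sunday=7
            "year": dates.year.to_numpy(),
            "is_holiday": dates.isin(holidays.holiday_dates),
            "is_new_years_day": dates.isin(holidays.dates_with_label("new_years_day")),
            "is_new_years_eve": dates.isin(holidays.dates_with_label("new_years_eve")),
            "is_coming_of_age_day": dates.isin(
                holidays.dates_with_label("coming_of_age_day")
            ),
        }
    )
    return out


def count_prefecture_days(start_date, end_date, n_regions: int) -> int:
    """Inclusive day count between two dates times the number of regions."""
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if start > end:
        raise ValueError("start_date must not be after end_date")
    return (int((end - start).days) + 1) * int(n_regions)


def load_holidays(path) -> HolidayCalendar:
    tab = pd.read_csv(path, comment="#")
    tab["date"] = pd.to_datetime(tab["date"])
    return HolidayCalendar(tab)


def read_panel(
    deaths_table,
    temperature_table,
    population_table,
    holiday_table,
    impute: bool = True,
) -> list[RegionPanel]:
    """Assemble one :class:`RegionPanel` per region from the four CSV tables.

    Tables may be paths or already-loaded DataFrames.  Yearly population and
    prop65 are broadcast to days.  A deaths date missing from the temperature
    table becomes a missing temperature, filled by :func:`impute_temperature`
    when ``impute`` is true (the default); an unimputable missing value raises
    naming region and date.
    """
    deaths = _as_df(deaths_table)
    temps = _as_df(temperature_table)
    pops = _as_df(population_table)
    holidays = (
        holiday_table
        if isinstance(holiday_table, HolidayCalendar)
        else load_holidays(holiday_table)
    )

    deaths = deaths.copy()
    deaths["date"] = pd.to_datetime(deaths["date"])
    temps = temps.copy()
    temps["date"] = pd.to_datetime(temps["date"])

    for name, tab in (("deaths", deaths), ("temperature", temps)):
        dup = tab.duplicated(subset=["region", "date"])
        if dup.any():
            r, d = tab.loc[dup, ["region", "date"]].iloc[0]
            raise ValueError(f"{name} table: duplicate row for region={r} date={d.date()}")

    panels = []
    for region, dsub in deaths.groupby("region", sort=True):
        dsub = dsub.sort_values("date").reset_index(drop=True)
        tsub = temps.loc[temps["region"] == region, ["date", "tmean_c"]]
        merged = dsub.merge(tsub, on="date", how="left")
        merged["year"] = merged["date"].dt.year
        psub = pops.loc[pops["region"] == region, ["year", "population", "prop65"]]
        missing_years = set(merged["year"]) - set(psub["year"])
        if missing_years:
            raise ValueError(
                f"region {region}: population table missing years {sorted(missing_years)}"
            )
        merged = merged.merge(psub, on="year", how="left")
        cal = build_calendar(pd.DatetimeIndex(merged["date"]), holidays)
        frame = pd.DataFrame(
            {
                "date": merged["date"],
                "deaths": merged["deaths"].astype(int),
                "tmean": merged["tmean_c"].astype(float),
                "population": merged["population"].astype(float),
                "prop65": merged["prop65"].astype(float),
            }
        )
        frame = pd.concat([frame, cal], axis=1)
        panel = RegionPanel(str(region), frame)
        if impute:
            panel = impute_temperature(panel)
        panels.append(panel)
    return panels


def impute_temperature(panel: RegionPanel) -> RegionPanel:
    """Fill missing temperatures from the same calendar date in earlier years.

    The imputed value is the arithmetic mean of the non-missing temperatures
    observed on the same (month, day) in strictly earlier years of the same
    region.  Observed values are never altered, so the operation is
    idempotent.  A missing value with no earlier-year donor (first year of the
    series, or February 29 with no earlier leap year) raises ``ValueError``.
    """
    df = panel.data
    tmean = df["tmean"].to_numpy(dtype=float).copy()
    missing = np.flatnonzero(np.isnan(tmean))
    if missing.size == 0:
        return panel
    dates = pd.DatetimeIndex(df["date"])
    month = dates.month.to_numpy()
    day = dates.day.to_numpy()
    year = dates.year.to_numpy()
    for i in missing:
        donors = (
            (month == month[i]) & (day == day[i]) & (year < year[i]) & ~np.isnan(tmean)
        )
        # donors drawn only from originally observed values: imputed entries in
        # earlier years were themselves donor means, but exclude them anyway by
        # iterating in date order (earlier rows are already final).
        if not donors.any():
            raise ValueError(
                f"region {panel.region_id}: missing temperature on "
                f"{dates[i].date()} has no earlier-year donor"
            )
        tmean[i] = float(np.mean(tmean[donors]))
    out = df.copy()
    out["tmean"] = tmean
    return RegionPanel(panel.region_id, out)


def write_panel_tables(panels: list[RegionPanel], holidays: HolidayCalendar, outdir) -> dict:
    """Write the module's CSV schemas; returns the paths written."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    deaths_rows, temp_rows, pop_rows = [], [], []
    for p in panels:
        d = p.data
        dates = pd.DatetimeIndex(d["date"]).strftime("%Y-%m-%d")
        deaths_rows.append(
            pd.DataFrame({"region": p.region_id, "date": dates, "deaths": d["deaths"]})
        )
        temp_rows.append(
            pd.DataFrame({"region": p.region_id, "date": dates, "tmean_c": d["tmean"]})
        )
        yearly = d.groupby("year")[["population", "prop65"]].first().reset_index()
        yearly.insert(0, "region", p.region_id)
        pop_rows.append(yearly)
    paths = {
        "deaths": outdir / "deaths.csv",
        "temperature": outdir / "temperature.csv",
        "population": outdir / "population.csv",
        "holidays": outdir / "holidays.csv",
    }
    pd.concat(deaths_rows).to_csv(paths["deaths"], index=False)
    pd.concat(temp_rows).to_csv(paths["temperature"], index=False)
    pd.concat(pop_rows).to_csv(paths["population"], index=False)
    htab = holidays.table.copy()
    htab["date"] = pd.DatetimeIndex(htab["date"]).strftime("%Y-%m-%d")
    htab.to_csv(paths["holidays"], index=False)
    return paths


def _as_df(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj
    return pd.read_csv(obj, comment="#")
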