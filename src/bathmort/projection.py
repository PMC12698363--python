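"""Future mortality projections under temperature and population scenarios.

The historical model is extended with the national proportion aged 65+ and a
linear calendar-year term, fitted on the national panel (regional deaths and
populations summed, temperatures and prop65 population-weighted).  Projected
daily expected deaths are then computed for every crossing of a temperature
pathway with a population trajectory over 2020-2069, summed by decade, and
expressed both per capita and relative to a baseline cell (the 2020s under
the intermediate population and the middle temperature pathway).

Projections are expected counts; an optional stochastic mode draws Poisson
decade totals for interval bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import CrossBasisSpec, CyclicBasisSpec, make_crossbasis
from .glm import FitResult, ModelSpec, build_design, fit_quasipoisson
from .panel import RegionPanel, build_calendar
from .simulate import ScenarioSet, make_holiday_calendar

__all__ = [
    "make_national_panel",
    "fit_projection_model",
    "project",
    "ProjectionModelInfo",
]


def make_national_panel(panels) -> RegionPanel:
    """Aggregate regional panels to one national panel.

    Deaths and population are summed; temperature and prop65 are
    population-weighted means across regions (a single representative
    national exposure series).
    """
    base = panels[0].data
    deaths = sum(p.data["deaths"].to_numpy() for p in panels)
    pops = np.column_stack([p.data["population"].to_numpy() for p in panels])
    temps = np.column_stack([p.data["tmean"].to_numpy() for p in panels])
    prop65 = np.column_stack([p.data["prop65"].to_numpy() for p in panels])
    wts = pops / pops.sum(axis=1, keepdims=True)
    frame = base.copy()
    frame["deaths"] = deaths
    frame["population"] = pops.sum(axis=1)
    frame["tmean"] = (temps * wts).sum(axis=1)
    frame["prop65"] = (prop65 * wts).sum(axis=1)
    return RegionPanel("national", frame)


@dataclass
class ProjectionModelInfo:
    """Fitted projection model plus the bookkeeping projection needs."""

    fit: FitResult
    crossbasis_spec: CrossBasisSpec
    seasonal_df: int
    year0: int  # origin of the linear year covariate


def fit_projection_model(
    panel: RegionPanel,
    crossbasis_spec: CrossBasisSpec | None = None,
    cb_history=None,
    seasonal_df: int = 4,
) -> ProjectionModelInfo:
    """Fit seasonal + cross-basis + prop65 + linear-year model on history."""
    prop65 = panel.data["prop65"].to_numpy()
    if np.ptp(prop65) == 0:
        raise ValueError("prop65 is constant over the fitting window: inestimable")
    if crossbasis_spec is None:
        crossbasis_spec = CrossBasisSpec.from_data(panel.data["tmean"].to_numpy())
    spec = ModelSpec(
        include_seasonal=True,
        include_crossbasis=True,
        calendar_terms=frozenset({"prop65", "linear_year"}),
        seasonal_df=seasonal_df,
    )
    d = build_design(panel, spec, crossbasis_spec, cb_history)
    fit = fit_quasipoisson(d.y, d.X, d.offset, d.column_names, d.column_roles)
    return ProjectionModelInfo(
        fit=fit,
        crossbasis_spec=crossbasis_spec,
        seasonal_df=seasonal_df,
        year0=int(panel.data["year"].min()),
    )


def _decade_label(year: int) -> str:
    return f"{(year // 10) * 10}s"


def project(
    info: ProjectionModelInfo,
    scenarios: ScenarioSet,
    baseline: tuple = ("2020s", "ssp245", "intermediate"),
    freeze_year: bool = False,
    n_draws: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Decade-aggregated projected deaths for every scenario crossing.

    Returns a long-format table keyed by (decade, temperature pathway,
    population trajectory) with projected deaths, deaths per population
    (decade deaths over mean decade population) and both quantities relative
    to the baseline cell.  ``freeze_year=True`` zeroes the fitted linear-year
    coefficient (pure demographic + climate projection).  With ``n_draws``
    positive, Poisson draws of the decade totals give 95% interval columns.
    """
    fit = info.fit
    coef = fit.coef.copy()
    if freeze_year:
        coef[fit.column_names.index("linear_year")] = 0.0
    cyc = CyclicBasisSpec(df=info.seasonal_df)
    rng = np.random.default_rng(seed)

    rows = []
    for pathway, temp_tab in scenarios.temperature.items():
        dates = pd.DatetimeIndex(temp_tab["date"])
        temps = temp_tab["tmean_c"].to_numpy(dtype=float)
        if np.isnan(temps).any():
            bad = dates[np.isnan(temps)][0]
            raise ValueError(f"pathway {pathway}: missing temperature on {bad.date()}")
        cal = build_calendar(dates, make_holiday_calendar(range(dates[0].year, dates[-1].year + 1)))
        B = cyc.evaluate(cal["doy"].to_numpy())
        cb = make_crossbasis(temps, info.crossbasis_spec, history=scenarios.history)
        years = cal["year"].to_numpy()
        for traj, pop_tab in scenarios.population.items():
            pop_map = pop_tab.set_index("year")
            missing = set(np.unique(years)) - set(pop_map.index)
            if missing:
                raise ValueError(f"trajectory {traj}: missing years {sorted(missing)}")
            pop = pop_map.loc[years, "population"].to_numpy(dtype=float)
            prop65 = pop_map.loc[years, "prop65"].to_numpy(dtype=float)
            X = np.hstack(
                [
                    np.ones((len(dates), 1)),
                    B,
                    cb.values,
                    prop65[:, None],
                    (years.astype(float) - info.year0)[:, None],
                ]
            )
            mu = np.exp(np.log(pop) + X @ coef)
            frame = pd.DataFrame(
                {"decade": [(y // 10) * 10 for y in years], "mu": mu, "pop": pop, "year": years}
            )
            for dec, sub in frame.groupby("decade"):
                total = float(sub["mu"].sum())
                mean_pop = float(sub.groupby("year")["pop"].first().mean())
                row = {
                    "decade": f"{dec}s",
                    "temperature_pathway": pathway,
                    "population_trajectory": traj,
                    "projected_deaths": total,
                    "deaths_per_population": total / mean_pop,
                }
                if n_draws > 0:
                    draws = rng.poisson(total, size=n_draws)
                    row["deaths_lo"], row["deaths_hi"] = np.percentile(draws, [2.5, 97.5])
                rows.append(row)

    table = pd.DataFrame(rows)
    b_dec, b_path, b_traj = baseline
    mask = (
        (table["decade"] == b_dec)
        & (table["temperature_pathway"] == b_path)
        & (table["population_trajectory"] == b_traj)
    )
    if not mask.any():
        raise ValueError(f"baseline cell {baseline} not present in the scenario set")
    base = table.loc[mask].iloc[0]
    table["relative_deaths"] = table["projected_deaths"] / base["projected_deaths"]
    table["relative_per_capita"] = (
        table["deaths_per_population"] / base["deaths_per_population"]
    )
    return table
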