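"""Model/Results front-end over the two-stage pipeline.

Three model classes mirror the study's three analyses:

* :class:`SeasonalMortalityModel` — per-region quasi-Poisson regression with
  a cyclic day-of-year spline (optionally plus the temperature cross-basis),
  pooled by multivariate meta-analysis.  Its results expose the seasonality
  summary (peak/trough, PTR, AF with Monte Carlo eCIs) and the pooled
  temperature response curves.
* :class:`DayTypeModel` — holiday / New Year / day-of-week relative risks,
  unadjusted and adjusted.
* :class:`ProjectionModel` — the extended national model and its
  decade-aggregated scenario projections.

Each ``fit()`` returns a Results object carrying estimates, covariances and
diagnostics, with ``summary()`` producing a readable table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import daytype as _daytype
from . import projection as _projection
from .basis import CrossBasisSpec
from .glm import FitResult, ModelSpec, fit_region
from .pooling import PooledEstimate, pool
from .seasonality import SeasonalitySummary, build_seasonal_curve, summarize_seasonality
from .temperature import TemperatureResponse, pooled_crossbasis_spec, pooled_temperature_curves

__all__ = [
    "SeasonalMortalityModel",
    "SeasonalMortalityResults",
    "DayTypeModel",
    "DayTypeResults",
    "ProjectionModel",
    "ProjectionResults",
]


class SeasonalMortalityModel:
    """Two-stage seasonal (and temperature) model over regional panels.

    Parameters
    ----------
    panels : list of RegionPanel
    seasonal_df : degrees of freedom of the cyclic day-of-year spline.
    adjust_temperature : include the temperature-lag cross-basis.
    crossbasis_spec : common cross-basis; built from the pooled temperature
        distribution when omitted.
    histories : optional dict region_id -> pre-period temperatures used to
        seed the lag window (otherwise the first max_lag days are dropped).
    extra_terms : additional calendar terms (e.g. {"prop65"}).
    """

    def __init__(
        self,
        panels,
        seasonal_df: int = 4,
        adjust_temperature: bool = False,
        crossbasis_spec: CrossBasisSpec | None = None,
        histories: dict | None = None,
        extra_terms=(),
    ):
        self.panels = list(panels)
        if not self.panels:
            raise ValueError("need at least one region panel")
        self.seasonal_df = seasonal_df
        self.adjust_temperature = adjust_temperature
        if adjust_temperature and crossbasis_spec is None:
            crossbasis_spec = pooled_crossbasis_spec(self.panels)
        self.crossbasis_spec = crossbasis_spec
        self.histories = histories or {}
        self.extra_terms = frozenset(extra_terms)

    def fit(
        self, pool_method: str = "reml", cb_pool_method: str = "mm"
    ) -> "SeasonalMortalityResults":
        spec = ModelSpec(
            include_seasonal=True,
            include_crossbasis=self.adjust_temperature,
            calendar_terms=self.extra_terms,
            seasonal_df=self.seasonal_df,
        )
        fits = []
        for p in self.panels:
            fits.append(
                fit_region(
                    p,
                    spec,
                    self.crossbasis_spec if self.adjust_temperature else None,
                    self.histories.get(p.region_id),
                )
            )
        seasonal_subs = [fr.subvector("seasonal") for fr in fits]
        pooled_seasonal = pool(
            seasonal_subs, method=pool_method if len(fits) > 1 else "fixed"
        )
        return SeasonalMortalityResults(
            model=self,
            region_fits=fits,
            pooled_seasonal=pooled_seasonal,
            cb_pool_method=cb_pool_method,
        )


@dataclass
class SeasonalMortalityResults:
    """Estimates and summaries of a fitted :class:`SeasonalMortalityModel`."""

    model: SeasonalMortalityModel
    region_fits: list
    pooled_seasonal: PooledEstimate
    cb_pool_method: str = "mm"
    _temperature: TemperatureResponse | None = field(default=None, repr=False)

    @property
    def dispersions(self) -> np.ndarray:
        return np.array([fr.dispersion for fr in self.region_fits])

    def seasonal_curve(self):
        return build_seasonal_curve(self.pooled_seasonal, df=self.model.seasonal_df)

    def seasonality(
        self, n_sim: int = 5000, seed: int = 0, weights=None
    ) -> SeasonalitySummary:
        return summarize_seasonality(
            self.pooled_seasonal,
            self.model.panels,
            df=self.model.seasonal_df,
            n_sim=n_sim,
            seed=seed,
            weights=weights,
        )

    def temperature(self, grid=None, lags=(0, 2, 7, 10)) -> TemperatureResponse:
        if not self.model.adjust_temperature:
            raise ValueError("model was fitted without the temperature cross-basis")
        if self._temperature is None or grid is not None:
            temps = np.concatenate(
                [p.data["tmean"].to_numpy() for p in self.model.panels]
            )
            self._temperature = pooled_temperature_curves(
                self.region_fits,
                self.model.crossbasis_spec,
                grid=grid,
                temps=temps,
                lags=lags,
                method=self.cb_pool_method,
            )
        return self._temperature

    def summary(self, n_sim: int = 2000, seed: int = 0) -> str:
        s = self.seasonality(n_sim=n_sim, seed=seed)
        lines = [
            "Seasonal mortality model (two-stage quasi-Poisson)",
            "=" * 52,
            f"regions: {len(self.region_fits)}    "
            f"obs/region: {self.region_fits[0].n_obs}",
            f"temperature-adjusted: {self.model.adjust_temperature}",
            f"dispersion: median {np.median(self.dispersions):.3f} "
            f"(range {self.dispersions.min():.3f}-{self.dispersions.max():.3f})",
            f"pooling: {self.pooled_seasonal.method} (k={self.pooled_seasonal.k})",
            "-" * 52,
            f"peak day-of-year:   {s.peak_doy:>4d}  eCI ({s.peak_eci[0]}, {s.peak_eci[1]})",
            f"trough day-of-year: {s.trough_doy:>4d}  eCI ({s.trough_eci[0]}, {s.trough_eci[1]})",
            f"peak-to-trough ratio: {s.ptr:.2f}  "
            f"95% CI ({s.ptr_ci[0]:.2f}, {s.ptr_ci[1]:.2f})",
            f"attributable fraction: {s.af_percent:.1f}%  "
            f"95% eCI ({s.af_eci[0]:.1f}, {s.af_eci[1]:.1f})",
        ]
        if self.model.adjust_temperature:
            tr = self.temperature()
            ref = tr.spec.reference_temp
            for t in (0.0, 30.0):
                lo, hi = tr.spec.var_boundary
                if lo <= t <= hi:
                    rr, ci = tr.rr_at(t)
                    lines.append(
                        f"cumulative RR at {t:.0f} degC (ref {ref:.1f}): "
                        f"{rr:.2f} ({ci[0]:.2f}, {ci[1]:.2f})"
                    )
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------
    def plot_seasonal(self, ax=None):
        """Seasonal RR curve over day-of-year."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.seasonal_curve()
        ax.plot(curve.doy, curve.rr)
        ax.set_xlabel("day of year")
        ax.set_ylabel("relative risk (vs. trough)")
        return ax

    def plot_temperature(self, ax=None):
        """Cumulative temperature-response curve with its 95% band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.temperature().cumulative
        ax.plot(c.grid, c.rr)
        ax.fill_between(c.grid, c.rr_low, c.rr_high, alpha=0.25)
        ax.axhline(1.0, lw=0.5, color="k")
        ax.set_xlabel("daily mean temperature (degC)")
        ax.set_ylabel("cumulative RR over lags")
        ax.set_yscale("log")
        return ax


class DayTypeModel:
    """Holiday / New Year / day-of-week relative-risk model."""

    def __init__(
        self,
        panels,
        crossbasis_spec: CrossBasisSpec | None = None,
        histories: dict | None = None,
    ):
        self.panels = list(panels)
        self.crossbasis_spec = crossbasis_spec or pooled_crossbasis_spec(self.panels)
        self.histories = histories or {}

    def fit(self, pool_method: str = "reml") -> "DayTypeResults":
        table = _daytype.daytype_table(
            self.panels, self.crossbasis_spec, self.histories, method=pool_method
        )
        return DayTypeResults(model=self, table=table)


@dataclass
class DayTypeResults:
    model: DayTypeModel
    table: object  # DataFrame shaped like the day-type results table

    def summary(self) -> str:
        lines = ["Day-type relative risks (pooled across regions)", "=" * 64]
        for _, r in self.table.iterrows():
            if np.isnan(r["adjusted_rr"]):
                lines.append(f"{r['term']:<28} Ref.")
                continue
            lines.append(
                f"{r['term']:<28} "
                f"unadj {r['unadjusted_rr']:.2f} ({r['unadjusted_lo']:.2f}-{r['unadjusted_hi']:.2f})  "
                f"adj {r['adjusted_rr']:.2f} ({r['adjusted_lo']:.2f}-{r['adjusted_hi']:.2f})"
            )
        return "\n".join(lines)


class ProjectionModel:
    """Extended national model for scenario projections."""

    def __init__(
        self,
        panels,
        crossbasis_spec: CrossBasisSpec | None = None,
        history=None,
        seasonal_df: int = 4,
    ):
        self.national = (
            panels if hasattr(panels, "region_id") else _projection.make_national_panel(panels)
        )
        self.crossbasis_spec = crossbasis_spec
        self.history = history
        self.seasonal_df = seasonal_df

    def fit(self) -> "ProjectionResults":
        info = _projection.fit_projection_model(
            self.national,
            crossbasis_spec=self.crossbasis_spec,
            cb_history=self.history,
            seasonal_df=self.seasonal_df,
        )
        return ProjectionResults(model=self, info=info)


@dataclass
class ProjectionResults:
    model: ProjectionModel
    info: _projection.ProjectionModelInfo

    @property
    def fit_result(self) -> FitResult:
        return self.info.fit

    def project(self, scenarios, **kw):
        return _projection.project(self.info, scenarios, **kw)

    def summary(self) -> str:
        fr = self.info.fit
        g, vg = fr.scalar("prop65")
        y, vy = fr.scalar("linear_year")
        return "\n".join(
            [
                "Projection model (national quasi-Poisson, extended)",
                "=" * 52,
                f"observations: {fr.n_obs}   dispersion: {fr.dispersion:.3f}",
                f"prop65 coefficient: {g:.3f} (SE {np.sqrt(vg):.3f})",
                f"linear-year coefficient: {y:.5f} (SE {np.sqrt(vy):.5f})",
            ]
        )
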