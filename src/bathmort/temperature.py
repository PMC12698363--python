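"""Pooled temperature-mortality association from region cross-basis fits.

Region-specific cross-basis coefficient vectors (all built on a common knot
placement from the pooled temperature distribution, so they are poolable)
are combined by multivariate meta-analysis and summarised as the overall
cumulative exposure-response curve, lag-specific slices, and the full
temperature x lag relative-risk surface, all against a common reference
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import CrossBasisSpec, ResponseCurve, predict_from_crossbasis
from .pooling import PooledEstimate, pool

__all__ = ["TemperatureResponse", "pooled_crossbasis_spec", "pooled_temperature_curves"]

DEFAULT_LAG_SLICES = (0, 2, 7, 10)


@dataclass
class TemperatureResponse:
    """Pooled cross-basis coefficients and the curves derived from them."""

    pooled: PooledEstimate
    spec: CrossBasisSpec
    cumulative: ResponseCurve
    lag_slices: dict
    surface: ResponseCurve

    def rr_at(self, temp: float) -> tuple[float, tuple[float, float]]:
        """Cumulative RR (and 95% CI) at one temperature."""
        c = predict_from_crossbasis(
            self.pooled.coef, self.pooled.vcov, self.spec, np.array([temp])
        )
        return float(c.rr[0]), (float(c.rr_low[0]), float(c.rr_high[0]))


def pooled_crossbasis_spec(
    panels,
    max_lag: int = 21,
    var_percentiles=(10.0, 75.0, 90.0),
    n_lag_knots: int = 3,
    reference_temp: float | None = None,
) -> CrossBasisSpec:
    """Common cross-basis spec with knots from the pooled temperatures.

    A shared knot placement across regions is what makes the region
    coefficient vectors commensurable for pooling; the reference defaults to
    the pooled median.
    """
    temps = np.concatenate([p.data["tmean"].to_numpy() for p in panels])
    return CrossBasisSpec.from_data(
        temps,
        max_lag=max_lag,
        var_percentiles=var_percentiles,
        n_lag_knots=n_lag_knots,
        reference_temp=reference_temp,
    )


def pooled_temperature_curves(
    fit_results,
    spec: CrossBasisSpec,
    grid: np.ndarray | None = None,
    temps: np.ndarray | None = None,
    lags=DEFAULT_LAG_SLICES,
    method: str = "mm",
) -> TemperatureResponse:
    """Pool cross-basis sub-vectors and emit cumulative/lag/surface curves.

    ``grid`` defaults to 1 degC steps spanning the 1st-99th percentiles of
    ``temps`` (or the spec's knot boundary when no temperatures are given);
    points outside the boundary are extrapolation and trigger a warning in
    prediction.
    """
    subs = []
    for fr in fit_results:
        b, V = fr.subvector("crossbasis")
        if len(b) != spec.n_cols:
            raise ValueError(
                f"cross-basis dimension mismatch: fit has {len(b)} columns, "
                f"spec expects {spec.n_cols}"
            )
        subs.append((b, V))
    pooled = pool(subs, method=method if len(subs) > 1 else "fixed")
    if grid is None:
        if temps is not None:
            lo, hi = np.percentile(np.asarray(temps, float), [1.0, 99.0])
        else:
            lo, hi = spec.var_boundary
        grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    grid = np.asarray(grid, float)
    cumulative = predict_from_crossbasis(pooled.coef, pooled.vcov, spec, grid)
    slices = {
        lag: predict_from_crossbasis(pooled.coef, pooled.vcov, spec, grid, at=lag)
        for lag in lags
    }
    surface = predict_from_crossbasis(pooled.coef, pooled.vcov, spec, grid, at="surface")
    return TemperatureResponse(
        pooled=pooled, spec=spec, cumulative=cumulative,
        lag_slices=slices, surface=surface,
    )
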