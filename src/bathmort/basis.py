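"""Spline bases: cyclic day-of-year spline and temperature-lag cross-basis.

Two basis families drive the regression design:

* a **cyclic cubic spline** of day-of-year (period 365) capturing seasonality,
  parameterised by its values at ``df`` evenly spaced cardinal knots — each
  basis column is the periodic cubic interpolant of one unit vector, so the
  basis is smooth (C2) across the year wrap by construction;

* a **cross-basis** — the tensor product of a natural cubic spline of
  temperature and a natural cubic spline of lag — whose row for day *t*
  combines basis-transformed temperatures at lags 0..L.  Its coefficients
  encode the full nonlinear exposure-lag surface of a distributed lag
  nonlinear model (DLNM), and linear contrasts of them give lag-specific and
  cumulative relative-risk curves against a reference temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "CyclicBasisSpec",
    "CrossBasisSpec",
    "BasisMatrix",
    "make_cyclic_basis",
    "make_crossbasis",
    "natural_cubic_basis",
    "predict_from_crossbasis",
    "ResponseCurve",
]


# ---------------------------------------------------------------------------
# cyclic day-of-year spline


@dataclass(frozen=True)
class CyclicBasisSpec:
    """Cyclic cubic spline of day-of-year with ``df`` free coefficients.

    Built from the cardinal basis on ``df + 1`` evenly spaced knots over the
    cycle (each cardinal function is the periodic cubic interpolant of one
    unit vector at the knots).  The cardinal functions sum to the constant 1,
    so the first is dropped for identifiability next to a model intercept —
    leaving ``df`` columns that, together with an intercept, span all
    periodic cubic splines on this knot set.
    """

    df: int = 4
    period: float = 365.0

    def __post_init__(self) -> None:
        if self.df < 3:
            raise ValueError("cyclic spline needs df >= 3")

    @property
    def knots(self) -> np.ndarray:
        n_knots = self.df + 1
        return 1.0 + self.period * np.arange(n_knots) / n_knots

    def evaluate(self, doy: np.ndarray, check: bool = True) -> np.ndarray:
        """n x df basis matrix at (possibly fractional) day-of-year values."""
        doy = np.asarray(doy, dtype=float)
        if check and ((doy < 1) | (doy > self.period)).any():
            bad = doy[(doy < 1) | (doy > self.period)]
            raise ValueError(f"day-of-year outside 1..{int(self.period)}: {bad[:5]}")
        k = self.knots
        x = np.append(k, k[0] + self.period)
        pos = (doy - k[0]) % self.period + k[0]
        cols = []
        for j in range(1, len(k)):  # cardinal 0 dropped: absorbed by intercept
            y = np.zeros(len(k) + 1)
            y[j] = 1.0
            cols.append(CubicSpline(x, y, bc_type="periodic")(pos))
        return np.column_stack(cols)


def make_cyclic_basis(doy_vector, spec: CyclicBasisSpec | None = None) -> "BasisMatrix":
    spec = spec or CyclicBasisSpec()
    values = spec.evaluate(np.asarray(doy_vector))
    names = [f"season_{j}" for j in range(spec.df)]
    return BasisMatrix(values=values, column_names=names, spec=spec)


# ---------------------------------------------------------------------------
# natural cubic spline (truncated-power construction, linear beyond boundaries)


def natural_cubic_basis(
    x: np.ndarray, knots: np.ndarray, intercept: bool = False
) -> np.ndarray:
    """Natural cubic spline basis with all knots given (boundary = first/last).

    Returns ``len(knots) - 1`` columns (plus an intercept column if
    requested): the identity term and K-2 truncated-power combinations that
    are linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    K = len(knots)
    if K < 2:
        raise ValueError("need at least two knots")

    def d(k):
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[-1], 0.0) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    if K > 2:
        dK1 = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dK1)
    out = np.column_stack(cols)
    if intercept:
        out = np.column_stack([np.ones_like(x), out])
    return out


# ---------------------------------------------------------------------------
# cross-basis


@dataclass(frozen=True)
class CrossBasisSpec:
    """Temperature x lag tensor-product basis specification.

    ``var_knots`` are internal temperature knots (default: 10th/75th/90th
    percentiles of the fitting data), ``var_boundary`` the observed range;
    ``lag_knots`` are internal lag knots, by default equally spaced on the
    log-lag scale between 1 and ``max_lag``.  The lag spline carries an
    intercept so an immediate-only effect is representable.
    """

    max_lag: int = 21
    var_knots: tuple = ()
    var_boundary: tuple = ()
    lag_knots: tuple = ()
    n_lag_knots: int = 3
    reference_temp: float = 0.0

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")

    @classmethod
    def from_data(
        cls,
        temps: np.ndarray,
        max_lag: int = 21,
        var_percentiles=(10.0, 75.0, 90.0),
        n_lag_knots: int = 3,
        reference_temp: float | None = None,
    ) -> "CrossBasisSpec":
        """Knots from the fitting data: percentile var knots, median reference."""
        temps = np.asarray(temps, dtype=float)
        temps = temps[~np.isnan(temps)]
        ref = float(np.median(temps)) if reference_temp is None else float(reference_temp)
        return cls(
            max_lag=max_lag,
            var_knots=tuple(np.percentile(temps, var_percentiles)),
            var_boundary=(float(temps.min()), float(temps.max())),
            n_lag_knots=n_lag_knots,
            reference_temp=ref,
        )

    @property
    def all_var_knots(self) -> np.ndarray:
        if not self.var_boundary:
            raise ValueError("var_boundary not set; build the spec from data")
        return np.sort(
            np.r_[self.var_boundary[0], list(self.var_knots), self.var_boundary[1]]
        )

    @property
    def all_lag_knots(self) -> np.ndarray:
        if self.lag_knots:
            inner = np.asarray(self.lag_knots, dtype=float)
        elif self.n_lag_knots > 0 and self.max_lag >= 2:
            inner = np.exp(
                np.linspace(np.log(1.0), np.log(self.max_lag), self.n_lag_knots + 2)
            )[1:-1]
        else:
            inner = np.array([])
        return np.sort(np.r_[0.0, inner, float(self.max_lag)])

    def var_basis(self, x: np.ndarray) -> np.ndarray:
        return natural_cubic_basis(x, self.all_var_knots)

    def lag_basis(self) -> np.ndarray:
        """(max_lag+1) x n_lag_cols matrix evaluated at lags 0..max_lag."""
        lags = np.arange(self.max_lag + 1, dtype=float)
        return natural_cubic_basis(lags, self.all_lag_knots, intercept=True)

    @property
    def n_var_cols(self) -> int:
        return len(self.all_var_knots) - 1

    @property
    def n_lag_cols(self) -> int:
        return len(self.all_lag_knots)  # K-1 spline cols + intercept

    @property
    def n_cols(self) -> int:
        return self.n_var_cols * self.n_lag_cols


@dataclass
class BasisMatrix:
    """Design-matrix block with column labels and the spec that produced it.

    ``complete`` flags rows with a full lag history (always all-true for the
    cyclic basis).
    """

    values: np.ndarray
    column_names: list[str]
    spec: object = None
    complete: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.complete is None:
            self.complete = np.ones(len(self.values), dtype=bool)
        if not np.isfinite(self.values[self.complete]).all():
            raise ValueError("non-finite basis entries in complete rows")

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


def make_crossbasis(
    temp_series,
    spec: CrossBasisSpec,
    history=None,
    drop_incomplete: bool = False,
) -> BasisMatrix:
    """Cross-basis matrix, row-aligned to ``temp_series``.

    Row *t* combines basis-transformed temperatures at lags 0..max_lag and is
    centred so that a constant exposure history at ``reference_temp`` maps to
    the zero vector.  ``history`` supplies at least ``max_lag`` temperatures
    preceding the first row; without it the first ``max_lag`` rows have no
    full history and are either flagged incomplete (``drop_incomplete=True``)
    or an error is raised.
    """
    temp = np.asarray(temp_series, dtype=float)
    L = spec.max_lag
    if history is not None:
        history = np.asarray(history, dtype=float)
        if len(history) < L:
            raise ValueError(f"history must supply at least {L} values")
        full = np.r_[history[len(history) - L :], temp] if L else temp
        offset = L
        complete = np.ones(len(temp), dtype=bool)
    else:
        if L > 0 and not drop_incomplete:
            raise ValueError(
                f"first {L} rows lack lag history; pass history= or drop_incomplete=True"
            )
        full = temp
        offset = 0
        complete = np.ones(len(temp), dtype=bool)
        complete[: min(L, len(temp))] = False

    V = spec.var_basis(full)  # (L + n) x pv
    W = spec.lag_basis()  # (L+1) x pl
    n = len(temp)
    pv, pl = V.shape[1], W.shape[1]
    cb = np.zeros((n, pv, pl))
    for lag in range(L + 1):
        lo = offset - lag
        rows = V[lo : lo + n] if lo >= 0 else np.vstack(
            [np.zeros((-lo, pv)), V[: lo + n]]
        )
        cb += rows[:, :, None] * W[lag][None, None, :]
    # centring: constant history at the reference temperature -> zero row
    vref = spec.var_basis(np.array([spec.reference_temp]))[0]
    wsum = W.sum(axis=0)
    cb -= (vref[:, None] * wsum[None, :])[None, :, :]
    values = cb.reshape(n, pv * pl)
    values[~complete] = np.nan
    names = [f"cb_v{j}_l{k}" for j in range(pv) for k in range(pl)]
    return BasisMatrix(values=values, column_names=names, spec=spec, complete=complete)


# ---------------------------------------------------------------------------
# prediction from fitted cross-basis coefficients


@dataclass
class ResponseCurve:
    """Relative-risk curve (or surface slice) with pointwise Wald intervals."""

    grid: np.ndarray  # temperature values (or (temp, lag) pairs for surface)
    log_rr: np.ndarray
    se: np.ndarray
    kind: str  # "cumulative", "lag:<l>" or "surface"
    reference_temp: float

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def rr_low(self) -> np.ndarray:
        return np.exp(self.log_rr - 1.96 * self.se)

    @property
    def rr_high(self) -> np.ndarray:
        return np.exp(self.log_rr + 1.96 * self.se)

    def to_frame(self):
        import pandas as pd

        if self.kind == "surface":
            return pd.DataFrame(
                {
                    "temperature": self.grid[:, 0],
                    "lag": self.grid[:, 1],
                    "rr": self.rr,
                    "rr_low": self.rr_low,
                    "rr_high": self.rr_high,
                }
            )
        return pd.DataFrame(
            {
                "temperature": self.grid,
                "rr": self.rr,
                "rr_low": self.rr_low,
                "rr_high": self.rr_high,
            }
        )


def crossbasis_contrast(
    spec: CrossBasisSpec, temps: np.ndarray, lag: int | None = None
) -> np.ndarray:
    """Contrast rows mapping coefficients to log-RR at given temperatures.

    ``lag=None`` gives the cumulative contrast (lag weights summed over the
    whole window); an integer selects one lag slice.
    """
    temps = np.asarray(temps, dtype=float)
    dv = spec.var_basis(temps) - spec.var_basis(np.array([spec.reference_temp]))
    W = spec.lag_basis()
    w = W.sum(axis=0) if lag is None else W[int(lag)]
    return (dv[:, :, None] * w[None, None, :]).reshape(len(temps), -1)


def predict_from_crossbasis(
    coef: np.ndarray,
    vcov: np.ndarray,
    spec: CrossBasisSpec,
    temp_grid: np.ndarray,
    at: str | int = "cumulative",
) -> ResponseCurve:
    """RR curve with delta-method CIs from cross-basis coefficients.

    ``at`` is ``"cumulative"``, an integer lag, or ``"surface"`` (all lags x
    grid).  Temperatures outside the spline support trigger an extrapolation
    warning, not an error.
    """
    coef = np.asarray(coef, dtype=float)
    if coef.shape[0] != spec.n_cols:
        raise ValueError(
            f"coefficient length {coef.shape[0]} != cross-basis columns {spec.n_cols}"
        )
    temp_grid = np.asarray(temp_grid, dtype=float)
    if spec.var_boundary:
        lo, hi = spec.var_boundary
        if ((temp_grid < lo) | (temp_grid > hi)).any():
            warnings.warn(
                "temperature grid extends beyond the spline support; "
                "curve values there are extrapolated",
                stacklevel=2,
            )
    if at == "surface":
        blocks, grid = [], []
        for lag in range(spec.max_lag + 1):
            blocks.append(crossbasis_contrast(spec, temp_grid, lag=lag))
            grid.append(np.column_stack([temp_grid, np.full_like(temp_grid, lag)]))
        C = np.vstack(blocks)
        grid = np.vstack(grid)
        kind = "surface"
    elif at == "cumulative":
        C = crossbasis_contrast(spec, temp_grid, lag=None)
        grid = temp_grid
        kind = "cumulative"
    else:
        C = crossbasis_contrast(spec, temp_grid, lag=int(at))
        grid = temp_grid
        kind = f"lag:{int(at)}"
    log_rr = C @ coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, vcov, C), 0.0))
    return ResponseCurve(
        grid=grid, log_rr=log_rr, se=se, kind=kind, reference_temp=spec.reference_temp
    )
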