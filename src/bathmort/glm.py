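"""Per-region quasi-Poisson regression with a log population offset.

The stage-one model for each region is

    deaths_t ~ quasiPoisson(mu_t),
    log mu_t = log P_t + intercept + s(doy_t) + cb(temp, lags 0..L) + calendar,

where ``P_t`` is the yearly population broadcast to days, ``s`` the cyclic
day-of-year spline and ``cb`` the temperature cross-basis.  Point estimates
solve the Poisson score equations; the dispersion (Pearson chi-square over
residual degrees of freedom) scales the covariance matrix only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .basis import BasisMatrix, CrossBasisSpec, CyclicBasisSpec, make_crossbasis
from .panel import DOW_REFERENCE, RegionPanel

__all__ = ["ModelSpec", "FitResult", "Design", "build_design", "fit_quasipoisson"]

_KNOWN_TERMS = {
    "dow_dummies",
    "year_dummies",
    "holiday_dummies",
    "dow_year_strata",
    "prop65",
    "linear_year",
}


@dataclass(frozen=True)
class ModelSpec:
    """Which design blocks enter the regression.

    ``calendar_terms`` is a subset of {dow_dummies, year_dummies,
    holiday_dummies, dow_year_strata, prop65, linear_year}.  Reference levels:
    Friday for day-of-week, the first observed year for year dummies and the
    (Friday, first-year) cell for the day-of-week x year strata.
    """

    include_seasonal: bool = True
    include_crossbasis: bool = False
    calendar_terms: frozenset = frozenset()
    seasonal_df: int = 4

    def __post_init__(self) -> None:
        terms = frozenset(self.calendar_terms)
        unknown = terms - _KNOWN_TERMS
        if unknown:
            raise ValueError(f"unknown calendar terms: {sorted(unknown)}")
        object.__setattr__(self, "calendar_terms", terms)
        if "dow_year_strata" in terms and terms & {"dow_dummies", "year_dummies"}:
            raise ValueError(
                "dow_year_strata absorbs day-of-week and year main effects; "
                "do not combine them"
            )


@dataclass
class Design:
    """Assembled regression inputs for one region."""

    X: np.ndarray
    y: np.ndarray
    offset: np.ndarray
    column_names: list[str]
    column_roles: dict[str, str]
    dates: object = None

    def columns_for(self, role: str) -> list[int]:
        return [i for i, n in enumerate(self.column_names) if self.column_roles[n] == role]


@dataclass
class FitResult:
    """Coefficients, dispersion-scaled covariance and column bookkeeping."""

    coef: np.ndarray
    vcov: np.ndarray
    dispersion: float
    n_obs: int
    df_resid: int
    column_names: list[str]
    column_roles: dict[str, str]
    converged: bool = True

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if len(self.coef) != len(self.column_names):
            raise ValueError("coef length != number of named columns")

    def columns_for(self, role: str) -> list[int]:
        return [i for i, n in enumerate(self.column_names) if self.column_roles[n] == role]

    def subvector(self, role: str) -> tuple[np.ndarray, np.ndarray]:
        """(coef, vcov) restricted to the columns playing one role."""
        idx = self.columns_for(role)
        if not idx:
            raise KeyError(f"no columns with role {role!r}")
        return self.coef[idx], self.vcov[np.ix_(idx, idx)]

    def scalar(self, name: str) -> tuple[float, float]:
        """(coefficient, variance) of one named column."""
        i = self.column_names.index(name)
        return float(self.coef[i]), float(self.vcov[i, i])

    def to_json(self) -> str:
        return json.dumps(
            {
                "coef": self.coef.tolist(),
                "vcov": self.vcov.tolist(),
                "dispersion": self.dispersion,
                "n_obs": self.n_obs,
                "df_resid": self.df_resid,
                "column_names": self.column_names,
                "column_roles": self.column_roles,
                "converged": self.converged,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        d = json.loads(text)
        return cls(
            coef=np.asarray(d["coef"]),
            vcov=np.asarray(d["vcov"]),
            dispersion=d["dispersion"],
            n_obs=d["n_obs"],
            df_resid=d["df_resid"],
            column_names=d["column_names"],
            column_roles=d["column_roles"],
            converged=d.get("converged", True),
        )


def _dow_dummies(dow: np.ndarray) -> tuple[np.ndarray, list[str]]:
    levels = [d for d in range(1, 8) if d != DOW_REFERENCE]
    cols = np.column_stack([(dow == d).astype(float) for d in levels])
    return cols, [f"dow_{d}" for d in levels]


def _holiday_indicators(df) -> tuple[np.ndarray, list[str]]:
    """Named-day indicators with precedence: the generic holiday flag is
    switched off on New Year's Day and Coming-of-Age Day so the three named
    effects are not double-counted."""
    nyd = df["is_new_years_day"].to_numpy(dtype=float)
    nye = df["is_new_years_eve"].to_numpy(dtype=float)
    coa = df["is_coming_of_age_day"].to_numpy(dtype=float)
    hol = df["is_holiday"].to_numpy(dtype=float) * (1 - nyd) * (1 - coa)
    cols = np.column_stack([hol, nyd, nye, coa])
    return cols, ["holiday", "new_years_day", "new_years_eve", "coming_of_age_day"]


def build_design(
    panel: RegionPanel,
    model_spec: ModelSpec,
    crossbasis_spec: CrossBasisSpec | None = None,
    cb_history=None,
) -> Design:
    """Assemble design matrix, offset and response for one region.

    Column order: intercept | seasonal | crossbasis | calendar.  Rows without
    a full lag history (when a cross-basis is included and no history series
    is supplied) are dropped from fitting.  A rank-deficient design raises,
    naming the collinear columns.
    """
    df = panel.data
    n = len(df)
    blocks = [np.ones((n, 1))]
    names = ["intercept"]
    roles = {"intercept": "intercept"}

    if model_spec.include_seasonal:
        cyc = CyclicBasisSpec(df=model_spec.seasonal_df)
        B = cyc.evaluate(df["doy"].to_numpy())
        blocks.append(B)
        for j in range(model_spec.seasonal_df):
            names.append(f"season_{j}")
            roles[f"season_{j}"] = "seasonal"

    keep = np.ones(n, dtype=bool)
    if model_spec.include_crossbasis:
        if crossbasis_spec is None:
            crossbasis_spec = CrossBasisSpec.from_data(df["tmean"].to_numpy())
        cb = make_crossbasis(
            df["tmean"].to_numpy(), crossbasis_spec,
            history=cb_history, drop_incomplete=cb_history is None,
        )
        blocks.append(cb.values)
        for nm in cb.column_names:
            names.append(nm)
            roles[nm] = "crossbasis"
        keep &= cb.complete

    terms = model_spec.calendar_terms
    if "dow_dummies" in terms:
        cols, nms = _dow_dummies(df["dow"].to_numpy())
        blocks.append(cols)
        for nm in nms:
            names.append(nm)
            roles[nm] = "dow"
    if "year_dummies" in terms:
        years = np.sort(df["year"].unique())
        cols = np.column_stack(
            [(df["year"].to_numpy() == y).astype(float) for y in years[1:]]
        )
        blocks.append(cols)
        for y in years[1:]:
            names.append(f"year_{y}")
            roles[f"year_{y}"] = "year"
    if "holiday_dummies" in terms:
        cols, nms = _holiday_indicators(df)
        blocks.append(cols)
        for nm in nms:
            names.append(nm)
            roles[nm] = "holiday"
    if "dow_year_strata" in terms:
        years = np.sort(df["year"].unique())
        dow = df["dow"].to_numpy()
        yr = df["year"].to_numpy()
        cols, nms = [], []
        for y in years:
            for d in range(1, 8):
                if y == years[0] and d == DOW_REFERENCE:
                    continue  # reference stratum
                cols.append(((yr == y) & (dow == d)).astype(float))
                nms.append(f"stratum_y{y}_d{d}")
        blocks.append(np.column_stack(cols))
        for nm in nms:
            names.append(nm)
            roles[nm] = "strata"
    if "prop65" in terms:
        blocks.append(df["prop65"].to_numpy()[:, None])
        names.append("prop65")
        roles["prop65"] = "prop65"
    if "linear_year" in terms:
        y0 = int(df["year"].min())
        blocks.append((df["year"].to_numpy(dtype=float) - y0)[:, None])
        names.append("linear_year")
        roles["linear_year"] = "linear_year"

    X = np.hstack(blocks)[keep]
    y = df["deaths"].to_numpy(dtype=float)[keep]
    offset = np.log(df["population"].to_numpy(dtype=float))[keep]
    dates = df["date"].to_numpy()[keep]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns beyond a pivoted-QR independent set
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[i] for i in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return Design(X=X, y=y, offset=offset, column_names=names, column_roles=roles, dates=dates)


def fit_quasipoisson(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    column_names: list[str] | None = None,
    column_roles: dict[str, str] | None = None,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> FitResult:
    """Quasi-Poisson fit: Poisson score equations, Pearson-scaled covariance.

    Estimation is iteratively reweighted least squares (via statsmodels GLM)
    to a relative deviance-change tolerance of ``tol``.  The dispersion never
    enters the point estimates.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if (y < 0).any():
        raise ValueError("response contains negative counts")
    if not y.any():
        raise ValueError("all-zero response: rate not estimable on the log scale")
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.asarray(offset, float))
    res = model.fit(scale="X2", maxiter=maxiter, tol=tol)
    converged = bool(res.converged)
    if not converged:
        # the IRLS stopping rule is absolute in the deviance; the contract is
        # relative, so accept when the trailing relative change is below tol
        trace = np.asarray(res.fit_history["deviance"][-3:], dtype=float)
        rel = np.abs(np.diff(trace)) / (np.abs(trace[-1]) + 1e-300)
        converged = bool(len(rel) and rel.max() < tol)
    if not converged:
        raise RuntimeError(
            f"IRLS did not converge in {maxiter} iterations "
            f"(deviance trace tail: {res.fit_history['deviance'][-3:]})"
        )
    names = column_names or [f"x{i}" for i in range(X.shape[1])]
    roles = column_roles or {n: "unknown" for n in names}
    return FitResult(
        coef=np.asarray(res.params),
        vcov=np.asarray(res.cov_params()),
        dispersion=float(res.scale),
        n_obs=int(len(y)),
        df_resid=int(res.df_resid),
        column_names=list(names),
        column_roles=roles,
        converged=converged,
    )


def fit_region(
    panel: RegionPanel,
    model_spec: ModelSpec,
    crossbasis_spec: CrossBasisSpec | None = None,
    cb_history=None,
) -> FitResult:
    """Build the design for one region and fit it in one call."""
    d = build_design(panel, model_spec, crossbasis_spec, cb_history)
    return fit_quasipoisson(d.y, d.X, d.offset, d.column_names, d.column_roles)
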