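"""Day-type relative risks: holidays, the New Year days, and day-of-week.

Each day-type target is estimated per region by quasi-Poisson regression and
pooled across regions by univariate random-effects meta-analysis.  Two model
families mirror the study design:

* **unadjusted** — intercept, offset and the target indicators only;
* **adjusted** — adds the cyclic seasonal spline and the temperature
  cross-basis; the holiday-target model further adds full day-of-week x year
  strata (absorbing both main effects), while the day-of-week target model
  adds holiday indicators and year dummies.

Named days have precedence over the generic holiday class: the holiday
indicator is switched off on New Year's Day and Coming-of-Age Day, so each
Table row contrasts that day type against regular days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .basis import CrossBasisSpec
from .glm import FitResult, ModelSpec, fit_region
from .panel import RegionPanel
from .pooling import pool

__all__ = ["DayTypeEffect", "daytype_model", "pool_daytype", "daytype_table"]

HOLIDAY_TERMS = ["holiday", "new_years_day", "new_years_eve", "coming_of_age_day"]
DOW_TERMS = ["dow_1", "dow_2", "dow_3", "dow_4", "dow_6", "dow_7"]  # Friday ref

TERM_LABELS = {
    "holiday": "Holiday (vs. Regular day)",
    "new_years_day": "New Year's Day",
    "new_years_eve": "New Year's Eve",
    "coming_of_age_day": "Coming-of-Age Day",
    "dow_1": "Monday",
    "dow_2": "Tuesday",
    "dow_3": "Wednesday",
    "dow_4": "Thursday",
    "dow_6": "Saturday",
    "dow_7": "Sunday",
}


@dataclass
class DayTypeEffect:
    term: str
    rr: float
    lo: float
    hi: float
    p_value: float
    model: str  # "unadjusted" | "adjusted"

    def __post_init__(self) -> None:
        if not (self.lo <= self.rr <= self.hi) or self.rr <= 0:
            raise ValueError(f"invalid interval for {self.term}")


def _check_targets_present(panel: RegionPanel, target: str) -> None:
    df = panel.data
    if target == "holiday_set":
        flags = {
            "holiday": df["is_holiday"].any(),
            "new_years_day": df["is_new_years_day"].any(),
            "new_years_eve": df["is_new_years_eve"].any(),
            "coming_of_age_day": df["is_coming_of_age_day"].any(),
        }
        missing = [k for k, v in flags.items() if not v]
        if missing:
            raise ValueError(
                f"region {panel.region_id}: day types absent from window: {missing}"
            )
    elif target == "dow":
        present = set(df["dow"].unique())
        if present != set(range(1, 8)):
            raise ValueError(
                f"region {panel.region_id}: days of week absent: "
                f"{sorted(set(range(1, 8)) - present)}"
            )
    else:
        raise ValueError(f"unknown day-type target {target!r}")


def daytype_model(
    panel: RegionPanel,
    target: str,
    adjusted: bool,
    crossbasis_spec: CrossBasisSpec | None = None,
    cb_history=None,
) -> FitResult:
    """Fit the per-region day-type model for one target family."""
    _check_targets_present(panel, target)
    if target == "holiday_set":
        terms = {"holiday_dummies"}
        if adjusted:
            terms |= {"dow_year_strata"}
    else:
        terms = {"dow_dummies"}
        if adjusted:
            terms |= {"holiday_dummies", "year_dummies"}
    spec = ModelSpec(
        include_seasonal=adjusted,
        include_crossbasis=adjusted,
        calendar_terms=frozenset(terms),
    )
    return fit_region(panel, spec, crossbasis_spec, cb_history)


def pool_daytype(
    fit_results, terms, model_label: str, method: str = "reml"
) -> list[DayTypeEffect]:
    """Univariate random-effects pooling of per-region scalar log-RRs."""
    out = []
    for term in terms:
        ests = []
        for fr in fit_results:
            b, v = fr.scalar(term)
            ests.append((np.array([b]), np.array([[v]])))
        pooled = pool(ests, method=method if len(ests) > 1 else "fixed")
        b = float(pooled.coef[0])
        se = float(np.sqrt(pooled.vcov[0, 0]))
        z = b / se if se > 0 else np.inf
        p = float(2 * stats.norm.sf(abs(z)))
        out.append(
            DayTypeEffect(
                term=term,
                rr=float(np.exp(b)),
                lo=float(np.exp(b - 1.96 * se)),
                hi=float(np.exp(b + 1.96 * se)),
                p_value=p,
                model=model_label,
            )
        )
    return out


def daytype_table(
    panels,
    crossbasis_spec: CrossBasisSpec | None = None,
    histories: dict | None = None,
    method: str = "reml",
) -> pd.DataFrame:
    """Full day-type table: unadjusted and adjusted RRs for every term.

    Returns one row per day type and day of week (Friday as the reference
    row), with RR, 95% CI bounds and two-sided Wald p-values for both model
    families.
    """
    effects = {}
    for target, terms in (("holiday_set", HOLIDAY_TERMS), ("dow", DOW_TERMS)):
        for adjusted, label in ((False, "unadjusted"), (True, "adjusted")):
            fits = [
                daytype_model(
                    p,
                    target,
                    adjusted,
                    crossbasis_spec if adjusted else None,
                    (histories or {}).get(p.region_id) if adjusted else None,
                )
                for p in panels
            ]
            for eff in pool_daytype(fits, terms, label, method=method):
                effects[(eff.term, label)] = eff

    rows = []
    ordered = HOLIDAY_TERMS + DOW_TERMS[:4] + ["friday_ref"] + DOW_TERMS[4:]
    for term in ordered:
        if term == "friday_ref":
            rows.append(
                {"term": "Friday", "unadjusted_rr": np.nan, "unadjusted_lo": np.nan,
                 "unadjusted_hi": np.nan, "unadjusted_p": np.nan,
                 "adjusted_rr": np.nan, "adjusted_lo": np.nan,
                 "adjusted_hi": np.nan, "adjusted_p": np.nan}
            )
            continue
        u = effects[(term, "unadjusted")]
        a = effects[(term, "adjusted")]
        rows.append(
            {
                "term": TERM_LABELS[term],
                "unadjusted_rr": u.rr, "unadjusted_lo": u.lo,
                "unadjusted_hi": u.hi, "unadjusted_p": u.p_value,
                "adjusted_rr": a.rr, "adjusted_lo": a.lo,
                "adjusted_hi": a.hi, "adjusted_p": a.p_value,
            }
        )
    return pd.DataFrame(rows)
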