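"""Kaplan-Meier summaries for the 1L-duration and TT2T endpoints.

Thin layer over :mod:`lifelines`: the product-limit estimate with
Greenwood variance, the median with a Brookmeyer-Crowley style 95% CI
obtained by inverting the pointwise log(-log) (exponential Greenwood)
confidence band at 0.5, and "NR" (not reached) propagation.  Medians are
computed in days and reported in months as days / 30.4375.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

DAYS_PER_MONTH = 30.4375
NOT_REACHED = float("inf")


@dataclass
class KMCurve:
    times: np.ndarray            # distinct event/censor times
    survival: np.ndarray         # S(t) at those times
    at_risk: np.ndarray
    n_events: np.ndarray
    variance: np.ndarray         # Greenwood Var[S(t)]
    n: int
    total_events: int
    _kmf: KaplanMeierFitter


@dataclass(frozen=True)
class KMSummary:
    median_days: float           # inf when not reached
    ci_low_days: float
    ci_high_days: float
    n: int
    n_events: int

    @property
    def median_months(self) -> float:
        return self.median_days / DAYS_PER_MONTH

    @property
    def ci_months(self) -> tuple[float, float]:
        return self.ci_low_days / DAYS_PER_MONTH, self.ci_high_days / DAYS_PER_MONTH

    @staticmethod
    def fmt(days: float) -> str:
        return "NR" if np.isinf(days) else f"{days / DAYS_PER_MONTH:.1f}"


def km_fit(time_days, event) -> KMCurve:
    """Product-limit fit; ties handled with events before censorings."""
    time = np.asarray(time_days, dtype=float)
    ev = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("no event-time records to fit")
    if (time < 0).any():
        raise ValueError("negative event times")
    kmf = KaplanMeierFitter()
    kmf.fit(time, ev)
    tbl = kmf.event_table[kmf.event_table.index > -1]
    times = tbl.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    at_risk = tbl["at_risk"].to_numpy()
    d = tbl["observed"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.where(at_risk > d, d / (at_risk * (at_risk - d)), 0.0)
    variance = surv**2 * np.cumsum(gw)
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=at_risk,
        n_events=d,
        variance=variance,
        n=int(time.size),
        total_events=int(ev.sum()),
        _kmf=kmf,
    )


def km_median_ci(curve: KMCurve, level: float = 0.95) -> KMSummary:
    """Median survival with CI from inverting the log(-log) band at 0.5."""
    kmf = curve._kmf
    if abs(level - (1 - kmf.alpha)) > 1e-12:
        kmf = KaplanMeierFitter(alpha=1 - level)
        kmf.fit(curve._kmf.durations, curve._kmf.event_observed)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo = float(ci.iloc[0, 0])
    hi = float(ci.iloc[0, 1])
    return KMSummary(
        median_days=median if np.isfinite(median) else NOT_REACHED,
        ci_low_days=lo if np.isfinite(lo) else NOT_REACHED,
        ci_high_days=hi if np.isfinite(hi) else NOT_REACHED,
        n=curve.n,
        n_events=curve.total_events,
    )


def km_summarize(time_days, event) -> KMSummary:
    return km_median_ci(km_fit(time_days, event))


def endpoint_summary_table(
    events: pd.DataFrame, cohort: pd.DataFrame
) -> pd.DataFrame:
    """Per-endpoint, per-stratum KM medians mirroring the treatment-patterns table.

    Strata: all patients, drug class (TK/VEGF vs mTOR), route, and agent.
    Output columns: endpoint, stratum, level, n, n_events, median_months,
    ci_low_months, ci_high_months (NaN-free; not-reached rendered inf).
    """
    merged = events.merge(
        cohort[["patient_id", "drug_class", "route", "index_agent"]], on="patient_id"
    )
    strata: list[tuple[str, str, pd.DataFrame]] = [("all", "all", merged)]
    for col, name in (
        ("drug_class", "class"), ("route", "route"), ("index_agent", "agent")
    ):
        for level, grp in merged.groupby(col, sort=True):
            if name == "class" and level == "IL2":
                continue
            strata.append((name, str(level), grp))
    rows = []
    for name, level, grp in strata:
        for endpoint, sub in grp.groupby("endpoint"):
            s = km_summarize(sub["time_days"], sub["event"])
            rows.append(
                {
                    "endpoint": endpoint, "stratum": name, "level": level,
                    "n": s.n, "n_events": s.n_events,
                    "median_months": s.median_months,
                    "ci_low_months": s.ci_months[0],
                    "ci_high_months": s.ci_months[1],
                }
            )
    return pd.DataFrame(rows)
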