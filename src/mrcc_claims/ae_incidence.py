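"""Incident, potentially treatment-related AEs: washout, person-time, IR.

For each adverse event (AE) of interest, a patient is *eligible* when no
claim matching the AE's code set appears in the pre-index washout window
(365 days for chronic conditions — hypertension, hypotension, hepatitis,
thyroid disorders, renal insufficiency, adrenal insufficiency,
myasthenia gravis — 30 days otherwise).  Washout-ineligible patients are
removed from both numerator and denominator for that AE only.

The at-risk window runs from the index date through 30 days after the
end of 1L treatment, bounded by the end of continuous enrollment.
Person-time accrues to the first matching claim (the onset) or, absent
one, to the end of the risk window; incidence is events per 100
person-years with an exact (Garwood) Poisson CI.  Onset latency is
summarized as median and Q1-Q3 in days using linear interpolation
(type-7) quartiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .claims_model import AEDefinition, ClaimsBundle
from .config import StudyConfig

DAY = pd.Timedelta(days=1)
DAYS_PER_YEAR = 365.25


def washout_eligible(
    dx_dates: np.ndarray, index_date: pd.Timestamp, ae: AEDefinition
) -> bool:
    """True unless a matching claim falls in ``[index - washout, index)``."""
    if dx_dates.size == 0:
        return True
    lo = np.datetime64((index_date - ae.washout_days * DAY).date())
    idx = np.datetime64(index_date.date())
    return not ((dx_dates >= lo) & (dx_dates < idx)).any()


def first_onset(
    dx_dates: np.ndarray, index_date: pd.Timestamp, risk_end: pd.Timestamp
) -> pd.Timestamp | None:
    """Earliest matching claim in ``[index, risk_end]`` (both inclusive)."""
    if dx_dates.size == 0:
        return None
    idx = np.datetime64(index_date.date())
    hi = np.datetime64(risk_end.date())
    hit = dx_dates[(dx_dates >= idx) & (dx_dates <= hi)]
    if hit.size == 0:
        return None
    return pd.Timestamp(hit.min())


def person_time_years(
    onset: pd.Timestamp | None, index_date: pd.Timestamp, risk_end: pd.Timestamp
) -> float:
    end = onset if onset is not None else risk_end
    days = (end - index_date).days
    if days < 0:
        raise ValueError("negative person-time interval")
    return days / DAYS_PER_YEAR


def poisson_exact_ci(k: int, level: float = 0.95) -> tuple[float, float]:
    """Garwood exact CI for a Poisson count (on the count scale)."""
    alpha = 1 - level
    lo = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2, 2 * k) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2
    return lo, hi


def incidence_rate(n_events: int, person_years: float, level: float = 0.95) -> dict:
    """IR per 100 PY with exact Poisson CI."""
    if person_years <= 0:
        raise ValueError("zero total person-years: rate undefined")
    lo, hi = poisson_exact_ci(n_events, level)
    scale = 100.0 / person_years
    return {
        "n_events": n_events,
        "person_years": person_years,
        "ir_per_100py": n_events * scale,
        "ci_low": lo * scale,
        "ci_high": hi * scale,
    }


def time_to_onset_summary(onset_days: np.ndarray) -> dict:
    """Median and Q1-Q3 (linear-interpolation quartiles), in days."""
    if onset_days.size == 0:
        raise ValueError("no onsets in stratum")
    q1, med, q3 = np.percentile(onset_days, [25, 50, 75])
    return {"n_onsets": int(onset_days.size), "median_days": float(med),
            "q1_days": float(q1), "q3_days": float(q3)}


def build_ae_observations(
    cohort: pd.DataFrame,
    episodes: pd.DataFrame,
    bundle: ClaimsBundle,
    config: StudyConfig,
) -> pd.DataFrame:
    """One row per (patient, AE): eligibility, onset day, person-years.

    The risk window ends 30 days after the line-1 episode end (identical
    to the duration endpoint's end-of-treatment), capped at enrollment end.
    """
    p = config.params
    if not config.ae_definitions:
        raise ValueError("no AE definitions configured")
    line1_end = (
        episodes[episodes["line"] == 1].set_index("patient_id")["end_date"]
    )
    med = bundle.medical
    med = med[med["kind"] == "dx"]
    code_values = med["code"].unique()
    empty = np.array([], dtype="datetime64[D]")
    # per-AE, per-patient claim-date arrays, built with one global pass per AE
    dates_by_ae: dict[str, dict[str, np.ndarray]] = {}
    for ae in config.ae_definitions:
        match = {c for c in code_values if c in ae.code_set}
        sub = med[med["code"].isin(match)]
        dates_by_ae[ae.ae_name] = {
            str(pid): g["date"].to_numpy(dtype="datetime64[D]")
            for pid, g in sub.groupby("patient_id", sort=False)
        }

    rows = []
    for rec in cohort.itertuples(index=False):
        pid = rec.patient_id
        index_date = rec.index_date
        risk_end = min(
            line1_end[pid] + p.ae_post_treatment_days * DAY, rec.followup_end
        )
        for ae in config.ae_definitions:
            dates = dates_by_ae[ae.ae_name].get(pid, empty)
            eligible = washout_eligible(dates, index_date, ae)
            onset = first_onset(dates, index_date, risk_end) if eligible else None
            py = person_time_years(onset, index_date, risk_end) if eligible else np.nan
            rows.append(
                {
                    "patient_id": pid,
                    "ae_name": ae.ae_name,
                    "eligible": eligible,
                    "onset_day": (onset - index_date).days if onset is not None else np.nan,
                    "person_years": py,
                }
            )
    return pd.DataFrame(rows)


def _strata(cohort: pd.DataFrame):
    yield "all", "all", pd.Series(True, index=cohort.index)
    for col, name in (
        ("drug_class", "class"), ("route", "route"), ("index_agent", "agent")
    ):
        for level in sorted(cohort[col].dropna().unique()):
            if name == "class" and level == "IL2":
                continue  # IL-2 patients appear in route/agent strata only
            yield name, str(level), cohort[col] == level


def incidence_table(
    observations: pd.DataFrame, cohort: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """IR per 100 PY with Poisson CI, per AE per stratum."""
    obs = observations.merge(
        cohort[["patient_id", "drug_class", "route", "index_agent"]], on="patient_id"
    )
    rows = []
    for sname, slevel, mask in _strata(cohort):
        pids = set(cohort.loc[mask, "patient_id"])
        sub = obs[obs["patient_id"].isin(pids) & obs["eligible"]]
        for ae_name, grp in sub.groupby("ae_name", sort=False):
            py = float(grp["person_years"].sum())
            k = int(grp["onset_day"].notna().sum())
            if py <= 0:
                continue
            r = incidence_rate(k, py, level)
            rows.append({"ae_name": ae_name, "stratum": sname, "level": slevel,
                         "n_eligible": len(grp), **r})
    return pd.DataFrame(rows)


def latency_table(observations: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Median (Q1-Q3) days to onset, per AE per stratum; absent strata omitted."""
    obs = observations.merge(
        cohort[["patient_id", "drug_class", "route", "index_agent"]], on="patient_id"
    )
    rows = []
    for sname, slevel, mask in _strata(cohort):
        pids = set(cohort.loc[mask, "patient_id"])
        sub = obs[obs["patient_id"].isin(pids) & obs["onset_day"].notna()]
        for ae_name, grp in sub.groupby("ae_name", sort=False):
            s = time_to_onset_summary(grp["onset_day"].to_numpy(dtype=float))
            rows.append({"ae_name": ae_name, "stratum": sname, "level": slevel, **s})
    return pd.DataFrame(rows)
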