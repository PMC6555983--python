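"""Eligibility cascade: from a claims bundle to the analysis cohort.

Implements the inclusion/exclusion logic for first-line (1L) targeted
therapy in metastatic renal cell carcinoma:

1. >= 2 kidney-cancer diagnosis claims (189.0 / C64.xx) on separate
   dates >= 30 days apart within the configured diagnosis window;
2. first-ever claim for a 1L study agent falling within 30 days before
   the first kidney-cancer claim through the end of the rolling index
   period — with the bevacizumab +/- IFN-alfa combination rule, the
   two-different-agents-within-5-days exclusion, and the rule that a
   different agent started within 30 days of the index and subsequently
   refilled replaces the index;
3. age >= 18 at index;
4. continuous enrollment 180 days pre- and post-index with no gap;
then exclusions: receipt of a TCC-indicated agent from 30 days pre-index
through follow-up end, and >= 2 baseline claims for another primary
cancer (excepting the sites RCC commonly metastasizes to, which are
deliberately absent from the configured code sets).

Baseline covariates (comorbidity flags, modified DCCI, metastatic-site
flags, nephrectomy) are evaluated over the 180-day pre-index window;
demographics come from the enrollment span covering the index date.
Rule internals run on numpy arrays: the cascade is evaluated per patient
and pandas row operations are too slow at realistic cohort sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .charlson import compute_dcci
from .claims_model import (
    BEVACIZUMAB,
    COMBINATION_AGENT,
    IFN_ALFA,
    ClaimsBundle,
    CodeSet,
    DrugCatalog,
)
from .config import RuleParameters, StudyConfig

log = logging.getLogger(__name__)

DAY = pd.Timedelta(days=1)
_D = np.timedelta64(1, "D")


def _d64(ts: pd.Timestamp) -> np.datetime64:
    return np.datetime64(ts, "ns")


@dataclass(frozen=True)
class IndexResult:
    index_date: pd.Timestamp
    index_agent: str
    five_day_excluded: bool = False
    replaced: bool = False


def find_mrcc_patients(
    bundle: ClaimsBundle,
    kidney: CodeSet,
    dx_window: tuple[pd.Timestamp, pd.Timestamp],
    min_days_apart: int = 30,
) -> dict[str, pd.Timestamp]:
    """Patients with >= 2 kidney-cancer dx claims >= ``min_days_apart`` apart.

    Returns ``{patient_id: first kidney-cancer claim date}`` (the anchor
    for the index-date rule).  The day-count boundary is inclusive.
    """
    med = bundle.medical
    med = med[med["kind"] == "dx"]
    if med.empty:
        return {}
    codes = pd.unique(med["code"])
    matching = {c for c in codes if c in kidney}
    lo, hi = dx_window
    mask = med["code"].isin(matching) & (med["date"] >= lo) & (med["date"] <= hi)
    med = med[mask]
    out: dict[str, pd.Timestamp] = {}
    for pid, grp in med.groupby("patient_id", sort=False):
        dates = np.unique(grp["date"].to_numpy())
        if len(dates) >= 2 and (dates[-1] - dates[0]) >= min_days_apart * _D:
            out[str(pid)] = pd.Timestamp(dates[0])
    return out


def determine_index(
    drug: pd.DataFrame,
    first_mrcc: pd.Timestamp,
    params: RuleParameters,
    catalog: DrugCatalog,
) -> IndexResult | None:
    """Index date/agent for one patient, or ``None`` if no qualifying claim.

    ``drug`` must contain only the patient's study-agent claims, sorted by
    date.  The rules compose in the order: combination merge, window
    check on the first-ever claim, 5-day two-agent exclusion, then the
    <= 30-day index-replacement rule (iterated, since the replacement can
    in principle itself be replaced).
    """
    if len(drug) == 0:
        return None
    dates = drug["date"].to_numpy()
    agents = drug["agent"].to_numpy()
    indexable = set(catalog.indexable_agents())

    firsts: dict[str, np.datetime64] = {}
    for a in pd.unique(agents):
        firsts[a] = dates[agents == a].min()

    # Combination regimen: bevacizumab and IFN-alfa first claims within
    # the combination window; indexed at the first occurring claim.
    comb_start = None
    if BEVACIZUMAB in firsts and IFN_ALFA in firsts:
        lo = min(firsts[BEVACIZUMAB], firsts[IFN_ALFA])
        hi = max(firsts[BEVACIZUMAB], firsts[IFN_ALFA])
        if (hi - lo) <= params.combination_window_days * _D:
            comb_start = lo

    candidates: dict[str, np.datetime64] = {
        a: d for a, d in firsts.items() if a in indexable
    }
    if comb_start is not None:
        candidates.pop(BEVACIZUMAB, None)
        candidates[COMBINATION_AGENT] = comb_start
    if not candidates:
        return None

    index_agent = min(candidates, key=lambda a: (candidates[a], a))
    index_date = candidates[index_agent]

    win_lo, win_hi = params.index_window
    if not (_d64(win_lo) <= index_date <= _d64(win_hi)):
        return None
    if index_date < _d64(first_mrcc) - 30 * _D:
        return None

    def _own_mask(agent: str) -> np.ndarray:
        if agent == COMBINATION_AGENT:
            return (agents == BEVACIZUMAB) | (agents == IFN_ALFA)
        return agents == agent

    # 5-day exclusion, evaluated at the original index.
    near = (dates <= index_date + params.five_day_exclusion_days * _D) & ~_own_mask(
        index_agent
    )
    if near.any():
        log.debug("patient excluded: two agents within 5 days at index %s", index_date)
        return IndexResult(
            pd.Timestamp(index_date), index_agent, five_day_excluded=True
        )

    # Index replacement: a different agent starting within 30 days of the
    # index, with a subsequent refill, becomes the 1L index drug.
    indexable_mask = np.isin(agents, sorted(indexable))
    replaced = False
    for _ in range(5):
        window = (
            (dates > index_date)
            & (dates <= index_date + params.index_replace_window_days * _D)
            & ~_own_mask(index_agent)
            & indexable_mask
        )
        if not window.any():
            break
        new_agent = agents[window][np.argmin(dates[window])]
        new_dates = dates[agents == new_agent]
        if len(new_dates) < 2:
            # no subsequent refill: the original index stands and this
            # agent is left to the switch logic
            break
        index_agent = new_agent
        index_date = new_dates.min()
        replaced = True
        log.debug("index replaced by %s at %s", new_agent, index_date)
        if index_agent == BEVACIZUMAB and IFN_ALFA in firsts:
            if abs(int((firsts[IFN_ALFA] - index_date) / _D)) <= params.combination_window_days:
                index_agent = COMBINATION_AGENT
                index_date = min(index_date, firsts[IFN_ALFA])
    return IndexResult(pd.Timestamp(index_date), index_agent, replaced=replaced)


def check_enrollment(
    enrollment: pd.DataFrame,
    index_date: pd.Timestamp,
    params: RuleParameters,
    *,
    require_post: bool = True,
) -> pd.Series | None:
    """The normalized span covering the continuous-enrollment window, if any.

    Requires one span covering ``[index - pre, index + post]`` (post
    optional for the cross-sectional trend cohort).  Returns the span row
    (demographics + ``end_date`` = end of continuous enrollment).
    """
    starts = enrollment["start_date"].to_numpy()
    ends = enrollment["end_date"].to_numpy()
    lo = _d64(index_date - params.enrollment_pre_days * DAY)
    hi = _d64(
        index_date + params.enrollment_post_days * DAY if require_post else index_date
    )
    ok = np.flatnonzero((starts <= lo) & (ends >= hi))
    if ok.size == 0:
        return None
    return enrollment.iloc[ok[0]]


def apply_exclusions(
    drug: pd.DataFrame,
    med_codes: pd.DataFrame,
    index_date: pd.Timestamp,
    followup_end: pd.Timestamp,
    config: StudyConfig,
) -> tuple[bool, list[str]]:
    """(included, reasons).  ``med_codes``: the patient's medical rows."""
    p = config.params
    reasons: list[str] = []
    if len(drug):
        dates = drug["date"].to_numpy()
        agents = drug["agent"].to_numpy()
        tcc = (
            np.isin(agents, config.tcc_agents)
            & (dates >= _d64(index_date - p.tcc_pre_index_days * DAY))
            & (dates <= _d64(followup_end))
        )
        if tcc.any():
            reasons.append("tcc_agent")
    if len(med_codes):
        mdates = med_codes["date"].to_numpy()
        mcodes = med_codes["code"].to_numpy()
        in_base = (mdates >= _d64(index_date - p.baseline_days * DAY)) & (
            mdates <= _d64(index_date)
        )
        base_codes = mcodes[in_base]
        for site, cs in config.other_primary.items():
            n = sum(c in cs for c in base_codes)
            if n >= 2:
                reasons.append(f"other_primary:{site}")
                break
    if reasons:
        log.debug("excluded at %s: %s", index_date, reasons)
    return (not reasons), reasons


def derive_baseline_covariates(
    med_codes: pd.DataFrame,
    index_date: pd.Timestamp,
    config: StudyConfig,
) -> dict:
    """Comorbidity flags, DCCI, metastatic-site flags, nephrectomy flag."""
    p = config.params
    out: dict = {}
    if len(med_codes):
        mdates = med_codes["date"].to_numpy()
        mcodes = med_codes["code"].to_numpy()
        mkind = med_codes["kind"].to_numpy()
        in_base = (
            (mdates >= _d64(index_date - p.baseline_days * DAY))
            & (mdates <= _d64(index_date))
            & (mkind == "dx")
        )
        dx = mcodes[in_base].tolist()
        pre_procs = mcodes[(mkind == "proc") & (mdates <= _d64(index_date))]
    else:
        dx = []
        pre_procs = np.array([], dtype=object)
    for name, cs in config.comorbidity.items():
        out[name] = any(c in cs for c in dx)
    out["dcci"] = compute_dcci(dx)
    for site, cs in config.metastasis.items():
        out[f"met_{site}"] = any(c in cs for c in dx)
    out["nephrectomy"] = any(c in config.nephrectomy_procedures for c in pre_procs)
    return out


CASCADE_LABELS = [
    "total_patients",
    "ge2_kidney_dx_claims",
    "first_line_agent_index",
    "age_ge_18",
    "continuous_enrollment",
    "no_tcc_agent",
    "no_other_primary_cancer",
]


def build_cohort(
    bundle: ClaimsBundle,
    config: StudyConfig,
    *,
    require_post_enrollment: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the full cascade; return (cohort table, attrition report).

    The attrition report lists patients remaining after each criterion in
    cascade order; counts are monotonically non-increasing.
    """
    p = config.params
    study_agents = set(config.catalog.agents)

    all_patients = bundle.patients()
    attrition: list[tuple[str, int]] = [("total_patients", len(all_patients))]

    mrcc = find_mrcc_patients(bundle, config.kidney, p.dx_window)
    attrition.append(("ge2_kidney_dx_claims", len(mrcc)))

    drug_by_pid = {
        str(pid): g.sort_values("date").reset_index(drop=True)
        for pid, g in bundle.drug.groupby("patient_id", sort=False)
    }
    med_by_pid = {
        str(pid): g for pid, g in bundle.medical.groupby("patient_id", sort=False)
    }
    enr_by_pid = {
        str(pid): g for pid, g in bundle.enrollment.groupby("patient_id", sort=False)
    }
    empty_med = bundle.medical.iloc[0:0]
    empty_drug = bundle.drug.iloc[0:0]

    study_mask_cache: dict[str, pd.DataFrame] = {}

    def study_claims(pid: str) -> pd.DataFrame:
        if pid not in study_mask_cache:
            d = drug_by_pid.get(pid, empty_drug)
            study_mask_cache[pid] = d[d["agent"].isin(study_agents)]
        return study_mask_cache[pid]

    indexed: dict[str, IndexResult] = {}
    for pid in sorted(mrcc):
        res = determine_index(study_claims(pid), mrcc[pid], p, config.catalog)
        if res is not None and not res.five_day_excluded:
            indexed[pid] = res
    attrition.append(("first_line_agent_index", len(indexed)))

    rows: list[dict] = []
    for pid, res in indexed.items():
        enr = enr_by_pid.get(pid)
        if enr is None:
            continue
        # age from the patient's enrollment record (stable across spans),
        # independent of whether the continuous-enrollment criterion holds
        birth_year = enr["birth_year"].iloc[0]
        if pd.isna(birth_year):
            continue
        age = int(res.index_date.year - int(birth_year))
        span = check_enrollment(
            enr, res.index_date, p, require_post=require_post_enrollment
        )
        rows.append(
            {
                "patient_id": pid,
                "index_date": res.index_date,
                "index_agent": res.index_agent,
                "age_at_index": age,
                "_span": span,
                "_enr": enr,
                "_replaced": res.replaced,
            }
        )
    adult = [r for r in rows if r["age_at_index"] >= 18]
    attrition.append(("age_ge_18", len(adult)))
    enrolled = [r for r in adult if r["_span"] is not None]
    attrition.append(("continuous_enrollment", len(enrolled)))

    no_tcc: list[dict] = []
    for r in enrolled:
        pid = r["patient_id"]
        followup_end = r["_span"]["end_date"]
        included, reasons = apply_exclusions(
            drug_by_pid.get(pid, empty_drug),
            med_by_pid.get(pid, empty_med),
            r["index_date"],
            followup_end,
            config,
        )
        if "tcc_agent" in reasons:
            continue
        r["_other_primary"] = any(x.startswith("other_primary") for x in reasons)
        r["followup_end"] = followup_end
        no_tcc.append(r)
    attrition.append(("no_tcc_agent", len(no_tcc)))
    final = [r for r in no_tcc if not r["_other_primary"]]
    attrition.append(("no_other_primary_cancer", len(final)))

    out_rows = []
    for r in final:
        pid = r["patient_id"]
        span = r["_span"]
        cls, route = config.catalog.classify_agent(r["index_agent"])
        cov = derive_baseline_covariates(
            med_by_pid.get(pid, empty_med), r["index_date"], config
        )
        rec = {
            "patient_id": pid,
            "index_date": r["index_date"],
            "index_agent": r["index_agent"],
            "drug_class": cls.value,
            "route": route.value,
            "index_year": int(r["index_date"].year),
            "age_at_index": r["age_at_index"],
            "sex": span["sex"],
            "region": span["region"],
            "employment": span["employment"],
            "plan_type": span["plan_type"],
            "insurance_type": span["insurance_type"],
            "index_replaced": bool(r["_replaced"]),
            "enrollment_end": span["end_date"],
            "followup_end": r["followup_end"],
        }
        rec.update(cov)
        out_rows.append(rec)

    cohort = pd.DataFrame(out_rows)
    if not cohort.empty:
        cohort = cohort.sort_values("patient_id").reset_index(drop=True)
        assert (cohort["age_at_index"] >= 18).all()
    report = pd.DataFrame(attrition, columns=["criterion", "patients_remaining"])
    assert report["patients_remaining"].is_monotonic_decreasing or len(report) <= 1
    return cohort, report
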