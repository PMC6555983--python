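"""Line-of-therapy engine: stitch drug claims into treatment episodes.

Coverage arithmetic follows the study definitions: an oral fill covers
``fill date + days supply``; an IV administration covers one labeled
cycle length.  Consecutive claims of the index regimen belong to one
episode while the uncovered gap (next claim date minus previous coverage
end) stays within the permitted <= 3-month (90-day) gap.  Coverage is
not stockpiled: each claim restarts coverage at its own date plus its
own supply/cycle.  A second line starts at the earlier of (a) the first
claim for a different agent strictly more than 30 days after the index
date, or (b) a restart of the index agent after a gap exceeding the
stitch threshold.

Event/censor pairs for the two Kaplan-Meier endpoints:

* duration of 1L — event at the episode end (or at the switch date if a
  2L starts before coverage ends) when a 2L exists, or when treatment
  was discontinued more than 90 days before the enrollment-eligibility
  end; otherwise censored at enrollment end;
* time to 2L (TT2T) — event at the 2L start; non-switchers censored at
  the earlier of episode end and enrollment end.

The bevacizumab + IFN-alfa combination is treated as a single regimen:
its episode is stitched on the union of both agents' claims.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .claims_model import (
    BEVACIZUMAB,
    COMBINATION_AGENT,
    IFN_ALFA,
    ClaimsBundle,
    DrugCatalog,
    Route,
)
from .config import StudyConfig

DAY = pd.Timedelta(days=1)
_D = np.timedelta64(1, "D")


def regimen_agents(agent: str) -> set[str]:
    """Concrete agents making up a (possibly combination) regimen."""
    return {BEVACIZUMAB, IFN_ALFA} if agent == COMBINATION_AGENT else {agent}


def _coverage_days_map(catalog: DrugCatalog) -> dict[str, int]:
    """Per-agent fixed coverage for IV agents; oral agents use days supply."""
    return {
        e.agent: int(e.cycle_length_days)
        for e in catalog
        if e.route is Route.IV
    }


def claim_coverage_end(
    claim_date: pd.Timestamp,
    agent: str,
    days_supply: float | None,
    catalog: DrugCatalog,
) -> pd.Timestamp:
    """Coverage end of one claim: date + days supply (oral) or cycle (IV)."""
    return claim_date + catalog.coverage_days(agent, days_supply) * DAY


@dataclass(frozen=True)
class StitchResult:
    start: pd.Timestamp
    end: pd.Timestamp          # coverage end of the last stitched claim
    n_claims: int
    restart_date: pd.Timestamp | None  # first own-agent claim after a > gap


def _coverage(agent: str, supply: float, iv_cover: dict[str, int], catalog) -> int:
    cov = iv_cover.get(agent)
    if cov is not None:
        return cov
    return catalog.coverage_days(agent, supply)


def _stitch(
    dates: np.ndarray,
    agents: np.ndarray,
    supplies: np.ndarray,
    index_date: np.datetime64,
    gap_days: int,
    catalog: DrugCatalog,
    iv_cover: dict[str, int],
) -> StitchResult:
    if len(dates) == 0 or dates[0] != index_date:
        raise ValueError("episode claims must be sorted with the first at the index date")
    end = dates[0] + _coverage(agents[0], supplies[0], iv_cover, catalog) * _D
    n = 1
    restart = None
    for i in range(1, len(dates)):
        if (dates[i] - end) > gap_days * _D:
            restart = pd.Timestamp(dates[i])
            break
        end = dates[i] + _coverage(agents[i], supplies[i], iv_cover, catalog) * _D
        n += 1
    return StitchResult(
        start=pd.Timestamp(index_date), end=pd.Timestamp(end), n_claims=n,
        restart_date=restart,
    )


def stitch_episode(
    claims: pd.DataFrame,
    index_date: pd.Timestamp,
    gap_days: int,
    catalog: DrugCatalog,
) -> StitchResult:
    """Stitch the index regimen's claims (sorted, first at index) into one episode.

    The first claim after an uncovered gap larger than ``gap_days``
    terminates the episode and is reported as a potential restart.
    """
    return _stitch(
        claims["date"].to_numpy(),
        claims["agent"].to_numpy(),
        claims["days_supply"].to_numpy(),
        np.datetime64(index_date, "ns"),
        gap_days,
        catalog,
        _coverage_days_map(catalog),
    )


def _detect_second_line(
    dates: np.ndarray,
    agents: np.ndarray,
    stitch: StitchResult,
    index_date: np.datetime64,
    index_agent: str,
    config: StudyConfig,
) -> tuple[int, str, pd.Timestamp] | None:
    p = config.params
    own = regimen_agents(index_agent)
    indexable = config.catalog.indexable_agents()

    own_mask = np.isin(agents, sorted(own))
    other = (
        ~own_mask
        & np.isin(agents, indexable)
        & (dates > index_date + p.switch_window_days * _D)
    )
    cand_date: np.datetime64 | None = None
    cand_agent: str | None = None
    if other.any():
        i = int(np.flatnonzero(other)[0])
        cand_date = dates[i]
        cand_agent = agents[i]
        if cand_agent == BEVACIZUMAB:
            ifn = (agents == IFN_ALFA) & (
                np.abs((dates - cand_date) / _D) <= p.combination_window_days
            )
            if ifn.any():
                cand_agent = COMBINATION_AGENT
    if stitch.restart_date is not None and (
        cand_date is None or np.datetime64(stitch.restart_date, "ns") < cand_date
    ):
        cand_date = np.datetime64(stitch.restart_date, "ns")
        cand_agent = index_agent  # restart of the index treatment
    if cand_date is None:
        return None
    return (
        int((cand_date - index_date) / _D),
        cand_agent,
        pd.Timestamp(cand_date),
    )


def detect_second_line(
    claims: pd.DataFrame,
    stitch: StitchResult,
    index_date: pd.Timestamp,
    index_agent: str,
    config: StudyConfig,
) -> tuple[int, str, pd.Timestamp] | None:
    """(tt2t_days, 2L agent, 2L start) or ``None``.

    ``claims``: all of the patient's study-agent claims, sorted by date.
    A different agent qualifies only strictly beyond the 30-day switch
    window; an index-agent restart after a gap > threshold qualifies at
    any time.  IFN-alfa alone never starts a line; a 2L bevacizumab
    claim with IFN-alfa inside the combination window is labeled as the
    combination.
    """
    return _detect_second_line(
        claims["date"].to_numpy(),
        claims["agent"].to_numpy(),
        stitch,
        np.datetime64(index_date, "ns"),
        index_agent,
        config,
    )


def duration_event(
    stitch: StitchResult,
    second_start: pd.Timestamp | None,
    index_date: pd.Timestamp,
    enrollment_end: pd.Timestamp,
    gap_days: int,
) -> tuple[int, bool, str]:
    """(time_days, event, end_reason) for the 1L-duration endpoint."""
    if second_start is not None:
        end = min(stitch.end, second_start)
        return int((end - index_date).days), True, "switch"
    if (enrollment_end - stitch.end).days > gap_days:
        return int((stitch.end - index_date).days), True, "discontinuation"
    return int((enrollment_end - index_date).days), False, "censored"


def tt2t_event(
    stitch: StitchResult,
    tt2t_days: int | None,
    index_date: pd.Timestamp,
    enrollment_end: pd.Timestamp,
) -> tuple[int, bool]:
    """(time_days, event) for the time-to-second-line endpoint."""
    if tt2t_days is not None:
        return tt2t_days, True
    censor = min(stitch.end, enrollment_end)
    return int((censor - index_date).days), False


def build_lines(
    cohort: pd.DataFrame, bundle: ClaimsBundle, config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full line-of-therapy reconstruction for every cohort patient.

    Returns ``(episodes, events)``: episodes has one row per treatment
    episode (line 1, and line 2 when present); events has one duration
    row and one tt2t row per patient (conservation holds by construction).
    """
    p = config.params
    study_agents = sorted(config.catalog.agents)
    iv_cover = _coverage_days_map(config.catalog)
    drug = bundle.drug[bundle.drug["agent"].isin(study_agents)]
    arrays_by_pid: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for pid, g in drug.groupby("patient_id", sort=False):
        g = g.sort_values("date")
        arrays_by_pid[str(pid)] = (
            g["date"].to_numpy(), g["agent"].to_numpy(), g["days_supply"].to_numpy()
        )

    ep_rows: list[dict] = []
    ev_rows: list[dict] = []
    for rec in cohort.itertuples(index=False):
        pid = rec.patient_id
        index_date = np.datetime64(rec.index_date, "ns")
        agent = rec.index_agent
        enrollment_end = rec.followup_end
        dates, agents, supplies = arrays_by_pid[pid]
        own = np.isin(agents, sorted(regimen_agents(agent))) & (dates >= index_date)
        st = _stitch(
            dates[own], agents[own], supplies[own], index_date, p.gap_days,
            config.catalog, iv_cover,
        )
        second = _detect_second_line(dates, agents, st, index_date, agent, config)
        tt2t_days, agent2, start2 = second if second else (None, None, None)

        dur_t, dur_e, reason = duration_event(
            st, start2, rec.index_date, enrollment_end, p.gap_days
        )
        tt_t, tt_e = tt2t_event(st, tt2t_days, rec.index_date, enrollment_end)

        ep_rows.append(
            {
                "patient_id": pid, "line": 1, "agent": agent,
                "start_date": rec.index_date,
                "end_date": min(st.end, start2) if start2 is not None else st.end,
                "coverage_end": st.end, "n_claims": st.n_claims,
                "end_reason": reason,
            }
        )
        if second is not None:
            start2_64 = np.datetime64(start2, "ns")
            own2 = np.isin(agents, sorted(regimen_agents(agent2))) & (
                dates >= start2_64
            )
            st2 = _stitch(
                dates[own2], agents[own2], supplies[own2], start2_64, p.gap_days,
                config.catalog, iv_cover,
            )
            reason2 = (
                "discontinuation"
                if (enrollment_end - st2.end).days > p.gap_days
                else "censored"
            )
            ep_rows.append(
                {
                    "patient_id": pid, "line": 2, "agent": agent2,
                    "start_date": start2, "end_date": st2.end,
                    "coverage_end": st2.end, "n_claims": st2.n_claims,
                    "end_reason": reason2,
                }
            )
        ev_rows.append(
            {"patient_id": pid, "endpoint": "duration", "time_days": dur_t, "event": dur_e}
        )
        ev_rows.append(
            {"patient_id": pid, "endpoint": "tt2t", "time_days": tt_t, "event": tt_e}
        )

    episodes = pd.DataFrame(ep_rows)
    events = pd.DataFrame(ev_rows)
    if not events.empty:
        assert (events["time_days"] >= 0).all()
    return episodes, events


def flow_table(cohort: pd.DataFrame, episodes: pd.DataFrame) -> pd.DataFrame:
    """Counts of 1L agent x (2L agent | none); each patient in exactly one cell."""
    first = cohort[["patient_id", "index_agent"]].rename(columns={"index_agent": "line1"})
    second = (
        episodes[episodes["line"] == 2][["patient_id", "agent"]]
        .rename(columns={"agent": "line2"})
    )
    merged = first.merge(second, on="patient_id", how="left")
    merged["line2"] = merged["line2"].fillna("none")
    table = (
        merged.groupby(["line1", "line2"]).size().unstack(fill_value=0).sort_index()
    )
    assert int(table.to_numpy().sum()) == len(cohort)
    return table
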