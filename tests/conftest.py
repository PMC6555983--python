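"""Shared fixtures: study config, in-memory bundle builders, hand fixture."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrcc_claims.claims_model import ClaimsBundle, normalize_enrollment_spans
from mrcc_claims.config import load_study_config

BASE = pd.Timestamp("2012-03-01")


def d(offset: int) -> pd.Timestamp:
    """Day ``offset`` relative to the fixture index anchor (2012-03-01)."""
    return BASE + pd.Timedelta(days=offset)


@pytest.fixture(scope="session")
def study():
    return load_study_config()


def make_bundle(enrollment, medical, drug) -> ClaimsBundle:
    """Build a normalized in-memory bundle from row dicts.

    enrollment rows: patient_id, start_date, end_date [+ demographics];
    medical rows: patient_id, date, code, kind; drug rows: patient_id,
    date, agent [, days_supply][, source].
    """
    enr = pd.DataFrame(enrollment)
    for col, default in (
        ("birth_year", 1952), ("sex", "M"), ("region", "south"),
        ("employment", "retiree"), ("plan_type", "PPO"),
        ("insurance_type", "commercial"),
    ):
        if col not in enr.columns:
            enr[col] = default
    enr["birth_year"] = enr["birth_year"].astype("Int64")
    enr = normalize_enrollment_spans(enr)

    med = pd.DataFrame(medical, columns=["patient_id", "date", "code", "kind"])
    med["claim_id"] = np.arange(len(med))
    med = med[["patient_id", "date", "claim_id", "code", "kind"]]
    med = med.sort_values(["patient_id", "date", "claim_id"]).reset_index(drop=True)

    dr = pd.DataFrame(drug, columns=["patient_id", "date", "agent", "days_supply", "source"])
    dr["days_supply"] = pd.to_numeric(dr["days_supply"])
    dr["source"] = dr["source"].fillna(
        dr["days_supply"].notna().map({True: "pharmacy", False: "administration"})
    )
    dr = dr.sort_values(["patient_id", "date"]).reset_index(drop=True)
    return ClaimsBundle(enrollment=enr, medical=med, drug=dr)


def rx(pid, date, agent, supply=30):
    return {"patient_id": pid, "date": date, "agent": agent,
            "days_supply": float(supply), "source": "pharmacy"}


def iv(pid, date, agent):
    return {"patient_id": pid, "date": date, "agent": agent,
            "days_supply": np.nan, "source": "administration"}


def dx(pid, date, code):
    return {"patient_id": pid, "date": date, "code": code, "kind": "dx"}


def proc(pid, date, code):
    return {"patient_id": pid, "date": date, "code": code, "kind": "proc"}


def hand_fixture_bundle() -> ClaimsBundle:
    """Ten hand-built patients exercising every eligibility and episode rule.

    P001 plain 30-day refills; P002 a 70-day permitted gap; P003 a
    120-day gap (restart-type second line); P004 a switch at day 120;
    P005 the two-agents-within-5-days exclusion; P006 the 30-day index
    replacement; P007 the bevacizumab+IFN combination; P008
    discontinuation within 90 days of enrollment end (censoring); P009
    TCC-agent exclusion; P010 other-primary-cancer exclusion.
    """
    pids = [f"P{i:03d}" for i in range(1, 11)]
    enrollment = []
    medical = []
    drug = []
    for pid in pids:
        end = d(250) if pid == "P008" else d(400)
        enrollment.append(
            {"patient_id": pid, "start_date": d(-400), "end_date": end}
        )
        medical += [dx(pid, d(-14), "1890"), dx(pid, d(31), "1890")]

    for off in (0, 30, 60):
        drug.append(rx("P001", d(off), "sunitinib"))
    drug += [rx("P002", d(0), "sunitinib"), rx("P002", d(100), "sunitinib")]
    drug += [rx("P003", d(0), "sunitinib"), rx("P003", d(150), "sunitinib")]
    drug += [rx("P004", d(0), "sunitinib"), rx("P004", d(120), "pazopanib"),
             rx("P004", d(150), "pazopanib")]
    drug += [rx("P005", d(0), "sunitinib"), rx("P005", d(3), "everolimus")]
    drug += [rx("P006", d(0), "sorafenib"), rx("P006", d(20), "pazopanib"),
             rx("P006", d(50), "pazopanib")]
    drug += [iv("P007", d(0), "ifn_alfa"), iv("P007", d(20), "bevacizumab"),
             iv("P007", d(34), "bevacizumab")]
    for off in range(0, 181, 30):
        drug.append(rx("P008", d(off), "sunitinib"))
    drug += [rx("P009", d(0), "sunitinib"), rx("P009", d(30), "sunitinib"),
             iv("P009", d(200), "gemcitabine")]
    drug += [rx("P010", d(0), "sunitinib")]
    medical += [dx("P010", d(-100), "174"), dx("P010", d(-50), "174")]

    return make_bundle(enrollment, medical, drug)


@pytest.fixture()
def hand_bundle() -> ClaimsBundle:
    return hand_fixture_bundle()
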