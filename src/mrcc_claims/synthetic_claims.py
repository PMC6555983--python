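"""Synthetic US commercial/Medicare-style claims with known ground truth.

Every downstream stage (cohort cascade, line-of-therapy stitching, KM
endpoints, AE incidence, choice model) gets a recovery test from this
generator: it emits the four claims tables *and* the latent truth that
produced them — true index date and agent, true 1L end, true 2L
start/agent, true AE onset times, true covariates and the treatment-
assignment log-odds.

Default parameters emulate the study population: index years 2011-2015,
~12% mTOR / ~88% TK-VEGF class mix with sunitinib and pazopanib
dominant, per-agent exponential treatment durations with medians of a
few months, 30-day oral fills with small refill gaps, IV administration
at the labeled cycle length, ~53% receiving a second line, and per-AE
constant hazards on the scale of the observed incidence rates.

Determinism: each patient draws from ``default_rng([seed, ordinal])``,
so records are reproducible independent of generation order and the
whole bundle is byte-identical for a fixed seed.

Switches are "clean" by construction: a different-agent 2L start is
placed at ``max(1L coverage end + delay, index + 31)`` so it always
satisfies the > 30-day switch rule, and restart-type second lines use an
uncovered gap strictly greater than the 90-day stitch threshold.  With
refill gaps below the threshold this makes the line-of-therapy rules
information-lossless, which is what the exact-recovery tests assert.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .claims_model import (
    BEVACIZUMAB,
    COMBINATION_AGENT,
    IFN_ALFA,
    ClaimsBundle,
    DrugClass,
    Route,
)
from .config import StudyConfig, load_study_config

DAY = pd.Timedelta(days=1)
LN2 = float(np.log(2.0))
DAYS_PER_MONTH = 30.4375


class SimConfigError(ValueError):
    pass


# Treatment-assignment model: log-odds of receiving mTOR- (vs TK/VEGF-)
# directed therapy.  Terms are covariate names, "const", or "year_YYYY".
DEFAULT_ASSIGNMENT_COEFS: dict[str, float] = {
    "const": -2.4,
    "chf": 0.9,
    "diabetes": -0.45,
    "met_bone": 0.45,
    "met_liver": 0.5,
    "year_2011": 0.55,
    "year_2012": 0.5,
}

DEFAULT_COVARIATE_PREVALENCE: dict[str, float] = {
    "diabetes": 0.27, "ckd": 0.20, "liver_disease": 0.18, "copd": 0.126,
    "chf": 0.075, "met_lung": 0.45, "met_liver": 0.11, "met_brain": 0.094,
    "met_bone": 0.28, "met_other": 0.40, "nephrectomy": 0.22,
}

DEFAULT_DURATION_MEDIAN_MONTHS: dict[str, float] = {
    "sunitinib": 6.5, "sorafenib": 4.7, "pazopanib": 7.0, "axitinib": 12.0,
    "bevacizumab": 2.8, COMBINATION_AGENT: 2.8, "everolimus": 4.0,
    "temsirolimus": 3.9, "aldesleukin": 2.0,
}

DEFAULT_TK_AGENT_MIX: dict[str, float] = {
    "sunitinib": 0.485, "pazopanib": 0.360, "bevacizumab": 0.085,
    "sorafenib": 0.037, "axitinib": 0.033,
}
DEFAULT_MTOR_AGENT_MIX: dict[str, float] = {"temsirolimus": 0.67, "everolimus": 0.33}

DEFAULT_SECOND_LINE_MIX: dict[str, float] = {
    "everolimus": 0.30, "axitinib": 0.21, "sunitinib": 0.13, "pazopanib": 0.13,
    "temsirolimus": 0.08, "bevacizumab": 0.08, "sorafenib": 0.05,
    "aldesleukin": 0.02,
}

#: per-AE pre-index prevalence and constant post-index hazards (events/PY)
DEFAULT_AE_MODEL: dict[str, dict[str, Any]] = {
    "nausea_vomiting": {"prevalence": 0.05, "hazard": {"TK_VEGF": 1.142, "MTOR": 3.645, "IL2": 1.1}},
    "hypertension": {"prevalence": 0.25, "hazard": {"TK_VEGF": 0.717, "MTOR": 0.478, "IL2": 0.6}},
    "diarrhea": {"prevalence": 0.02, "hazard": {"TK_VEGF": 0.299, "MTOR": 0.131, "IL2": 0.3}},
    "fatigue_asthenia": {"prevalence": 0.05, "hazard": {"TK_VEGF": 0.382, "MTOR": 0.552, "IL2": 0.4}},
    "anemia": {"prevalence": 0.08, "hazard": {"TK_VEGF": 0.354, "MTOR": 1.003, "IL2": 0.5}},
    "renal_insufficiency": {"prevalence": 0.10, "hazard": {"TK_VEGF": 0.423, "MTOR": 0.608, "IL2": 0.5}},
    "thyroid_disorders": {"prevalence": 0.08, "hazard": {"TK_VEGF": 0.219, "MTOR": 0.149, "IL2": 0.2}},
    "hypotension": {"prevalence": 0.03, "hazard": {"TK_VEGF": 0.076, "MTOR": 0.072, "IL2": 0.2}},
    "hepatitis": {"prevalence": 0.02, "hazard": {"TK_VEGF": 0.091, "MTOR": 0.110, "IL2": 0.05}},
    "adrenal_insufficiency": {"prevalence": 0.01, "hazard": {"TK_VEGF": 0.058, "MTOR": 0.104, "IL2": 0.05}},
    "myasthenia_gravis": {"prevalence": 0.002, "hazard": {"TK_VEGF": 0.0, "MTOR": 0.0, "IL2": 0.0}},
    "rash": {"prevalence": 0.03, "hazard": {"TK_VEGF": 0.095, "MTOR": 0.143, "IL2": 0.1}},
}

DEFAULT_INDEX_YEAR_WEIGHTS = {2011: 0.215, 2012: 0.21, 2013: 0.21, 2014: 0.185, 2015: 0.18}


@dataclass
class SimConfig:
    """Generator knobs; defaults are the emulated study conditions."""

    n_patients: int = 1000
    seed: int = 0
    index_year_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEX_YEAR_WEIGHTS)
    )
    il2_prob: float = 0.006
    tk_agent_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TK_AGENT_MIX))
    mtor_agent_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MTOR_AGENT_MIX))
    bev_combo_frac: float = 0.03
    second_line_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SECOND_LINE_MIX)
    )
    duration_median_months: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_MEDIAN_MONTHS)
    )
    duration_fixed_days: dict[str, int] = field(default_factory=dict)
    second_line_median_months: float = 4.0
    oral_days_supply: int = 30
    refill_gap_max_days: int = 10
    switch_prob: float = 0.528
    restart_frac: float = 0.10
    switch_delay_mean_days: float = 60.0
    restart_extra_gap_mean_days: float = 30.0
    followup_extra_mean_days: float = 330.0
    assignment_coefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ASSIGNMENT_COEFS)
    )
    covariate_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCE)
    )
    age_mean: float = 62.0
    age_sd: float = 11.0
    frac_female: float = 0.30
    ae_model: dict[str, dict[str, Any]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AE_MODEL.items()}
    )
    ae_pre_window_close_prob: float = 0.3  # pre-existing claim lands inside 30 d
    # ineligible-patient fractions, to exercise the attrition cascade
    frac_single_dx: float = 0.0
    frac_underage: float = 0.0
    frac_enrollment_gap: float = 0.0
    frac_tcc: float = 0.0
    frac_other_primary: float = 0.0
    frac_five_day: float = 0.0
    frac_index_replacement: float = 0.0

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_patients < 1:
            bad.append("n_patients")
        probs = {
            "il2_prob": self.il2_prob, "bev_combo_frac": self.bev_combo_frac,
            "switch_prob": self.switch_prob, "restart_frac": self.restart_frac,
            "frac_female": self.frac_female,
            "ae_pre_window_close_prob": self.ae_pre_window_close_prob,
        }
        for name in ("frac_single_dx", "frac_underage", "frac_enrollment_gap",
                     "frac_tcc", "frac_other_primary", "frac_five_day",
                     "frac_index_replacement"):
            probs[name] = getattr(self, name)
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                bad.append(name)
        for name, mix in (
            ("index_year_weights", self.index_year_weights),
            ("tk_agent_mix", self.tk_agent_mix),
            ("mtor_agent_mix", self.mtor_agent_mix),
            ("second_line_mix", self.second_line_mix),
        ):
            if not mix or any(w < 0 for w in mix.values()) or sum(mix.values()) <= 0:
                bad.append(name)
        for name, cfg in self.ae_model.items():
            if not (0 <= cfg.get("prevalence", 0) <= 1):
                bad.append(f"ae_model[{name}].prevalence")
            if any(h < 0 for h in cfg.get("hazard", {}).values()):
                bad.append(f"ae_model[{name}].hazard")
        if bad:
            raise SimConfigError(f"invalid simulation config field(s): {sorted(set(bad))}")


def _weighted_choice(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = list(mix)
    w = np.array([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def patient_rng(seed: int, ordinal: int) -> np.random.Generator:
    return np.random.default_rng([seed, ordinal])


def draw_covariates(rng: np.random.Generator, cfg: SimConfig) -> dict[str, Any]:
    cov: dict[str, Any] = {
        name: bool(rng.random() < p) for name, p in cfg.covariate_prevalence.items()
    }
    cov["age"] = int(np.clip(round(rng.normal(cfg.age_mean, cfg.age_sd)), 30, 90))
    cov["sex"] = "F" if rng.random() < cfg.frac_female else "M"
    cov["region"] = _weighted_choice(
        rng, {"northeast": 0.18, "north_central": 0.26, "south": 0.37,
              "west": 0.17, "unknown": 0.02}
    )
    cov["employment"] = _weighted_choice(
        rng, {"active": 0.32, "retiree": 0.37, "long_term_disability": 0.01,
              "other": 0.30}
    )
    cov["plan_type"] = _weighted_choice(
        rng, {"PPO": 0.53, "comprehensive": 0.18, "HMO": 0.11, "POS": 0.07,
              "other": 0.11}
    )
    cov["insurance_type"] = "medicare" if rng.random() < 0.36 else "commercial"
    return cov


def assignment_logit(cov: dict[str, Any], year: int, coefs: dict[str, float]) -> float:
    """Log-odds of mTOR-class assignment for one patient."""
    z = coefs.get("const", 0.0)
    for term, beta in coefs.items():
        if term == "const":
            continue
        if term.startswith("year_"):
            z += beta * (year == int(term.split("_")[1]))
        elif term == "age":
            z += beta * cov["age"]
        elif term == "sex_f":
            z += beta * (cov["sex"] == "F")
        else:
            z += beta * bool(cov.get(term, False))
    return float(z)


def assign_treatment(
    rng: np.random.Generator, cov: dict[str, Any], year: int, cfg: SimConfig
) -> tuple[str, float]:
    """(index agent, assignment log-odds).  IL-2 drawn first, then class."""
    z = assignment_logit(cov, year, cfg.assignment_coefs)
    if rng.random() < cfg.il2_prob:
        return "aldesleukin", z
    p_mtor = 1.0 / (1.0 + np.exp(-z))
    if rng.random() < p_mtor:
        return _weighted_choice(rng, cfg.mtor_agent_mix), z
    agent = _weighted_choice(rng, cfg.tk_agent_mix)
    if agent == BEVACIZUMAB and rng.random() < cfg.bev_combo_frac:
        agent = COMBINATION_AGENT
    return agent, z


def _duration_days(rng: np.random.Generator, agent: str, cfg: SimConfig) -> int:
    if agent in cfg.duration_fixed_days:
        return int(cfg.duration_fixed_days[agent])
    median = cfg.duration_median_months.get(agent, 6.0) * DAYS_PER_MONTH
    d = max(1, int(round(rng.exponential(median / LN2))))
    if agent == COMBINATION_AGENT:
        d = max(d, 8)  # the IFN-alfa partner claim lands on day 7
    return d


def _realize_regimen(
    rng: np.random.Generator,
    agent: str,
    start: pd.Timestamp,
    duration_days: int,
    limit: pd.Timestamp,
    cfg: SimConfig,
    study: StudyConfig,
) -> tuple[list[dict], pd.Timestamp | None]:
    """Emit the fill/administration claims for one regimen.

    Returns (claims, coverage end of the chronologically last claim), the
    latter being the regimen's true end under the no-stockpiling rule.
    """
    claims: list[dict] = []
    members = (
        [(BEVACIZUMAB, 0), (IFN_ALFA, 7)] if agent == COMBINATION_AGENT else [(agent, 0)]
    )
    last_claim: tuple[pd.Timestamp, int] | None = None  # (date, coverage days)
    for member, offset in members:
        entry = study.catalog.entry(member)
        t = offset
        while t < duration_days:
            date = start + t * DAY
            if date > limit:
                break
            if entry.route is Route.ORAL:
                supply = cfg.oral_days_supply
                claims.append(
                    {"date": date, "agent": member, "days_supply": float(supply),
                     "source": "pharmacy"}
                )
                step = supply + int(rng.integers(0, cfg.refill_gap_max_days + 1))
                cover = supply
            else:
                cover = int(entry.cycle_length_days)
                claims.append(
                    {"date": date, "agent": member, "days_supply": np.nan,
                     "source": "administration"}
                )
                step = cover
            if last_claim is None or date > last_claim[0]:
                last_claim = (date, cover)
            t += step
    if last_claim is None:
        return claims, None
    return claims, last_claim[0] + last_claim[1] * DAY


def generate_ae_history(
    rng: np.random.Generator,
    index_date: pd.Timestamp,
    enrollment_end: pd.Timestamp,
    drug_class: str,
    cfg: SimConfig,
    study: StudyConfig,
) -> tuple[list[dict], list[dict]]:
    """(medical dx claims, truth rows) for every configured AE.

    Pre-existing disease (with the configured prevalence) yields one
    pre-index claim placed either inside the 30-day window or in the
    31-365-day band, so both washout widths are exercised.  Post-index
    first onsets are exponential waiting times at the class hazard; the
    claim is emitted whenever it falls inside enrollment, regardless of
    the analysis risk window (the incidence engine must truncate).
    """
    med: list[dict] = []
    truth: list[dict] = []
    for ae_name, model in cfg.ae_model.items():
        try:
            code = study.ae(ae_name).code_set.prefixes[0]
        except KeyError:
            continue
        pre = rng.random() < model.get("prevalence", 0.0)
        pre_offset = None
        if pre:
            if rng.random() < cfg.ae_pre_window_close_prob:
                pre_offset = int(rng.integers(1, 31))
            else:
                pre_offset = int(rng.integers(31, 366))
            med.append({"date": index_date - pre_offset * DAY, "code": code, "kind": "dx"})
        hazard = float(model.get("hazard", {}).get(drug_class, 0.0))
        onset_day = None
        if hazard > 0:
            onset_day = int(round(rng.exponential(1.0 / hazard) * 365.25))
            if onset_day <= (enrollment_end - index_date).days:
                med.append({"date": index_date + onset_day * DAY,
                            "code": code, "kind": "dx"})
            else:
                onset_day = None  # onset after disenrollment: unobservable
        truth.append(
            {"ae_name": ae_name, "pre_existing": pre, "pre_offset_days": pre_offset,
             "onset_day": onset_day}
        )
    return med, truth


@dataclass
class GroundTruth:
    patients: pd.DataFrame  # one row per patient: truth of index/lines/covariates
    ae: pd.DataFrame        # one row per (patient, AE)


def generate(config: SimConfig, study: StudyConfig | None = None) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate a claims bundle plus its ground truth."""
    config.validate()
    study = study or load_study_config()
    win_lo, win_hi = study.params.index_window
    years = sorted(config.index_year_weights)
    yw = np.array([config.index_year_weights[y] for y in years], dtype=float)
    yw = yw / yw.sum()

    enr_rows: list[dict] = []
    med_rows: list[dict] = []
    drug_rows: list[dict] = []
    truth_rows: list[dict] = []
    ae_truth_rows: list[dict] = []

    decoy_pool = ["sorafenib", "sunitinib"]
    kidney_code = study.kidney.prefixes[0]  # "1890"

    for i in range(config.n_patients):
        rng = patient_rng(config.seed, i)
        pid = f"P{i:06d}"

        year = int(years[rng.choice(len(years), p=yw)])
        y0 = pd.Timestamp(year=year, month=1, day=1)
        ndays = int((pd.Timestamp(year=year + 1, month=1, day=1) - y0).days)
        index_date = y0 + int(rng.integers(0, ndays)) * DAY
        index_date = min(max(index_date, win_lo), win_hi)

        cov = draw_covariates(rng, config)
        agent, logit = assign_treatment(rng, cov, year, config)
        drug_class = study.catalog.classify_agent(agent)[0].value
        route = study.catalog.classify_agent(agent)[1].value

        # which (at most one) ineligibility fault this patient carries
        fault = None
        u = rng.random()
        acc = 0.0
        for name in ("single_dx", "underage", "enrollment_gap", "tcc",
                     "other_primary", "five_day"):
            acc += getattr(config, f"frac_{name}")
            if u < acc:
                fault = name
                break
        replacement = (
            fault is None
            and agent != COMBINATION_AGENT
            and rng.random() < config.frac_index_replacement
            and index_date - 20 * DAY >= win_lo
        )

        age = 16 if fault == "underage" else cov["age"]
        followup = 180 + int(round(rng.exponential(config.followup_extra_mean_days)))
        # lead-in always covers the 365-day washout look-back
        enr_start = index_date - (380 + int(rng.integers(0, 541))) * DAY
        enr_end = index_date + followup * DAY
        base_enr = {
            "patient_id": pid, "birth_year": year - age, "sex": cov["sex"],
            "region": cov["region"], "employment": cov["employment"],
            "plan_type": cov["plan_type"], "insurance_type": cov["insurance_type"],
        }
        if fault == "enrollment_gap":
            enr_rows.append({**base_enr, "start_date": enr_start, "end_date": index_date - 100 * DAY})
            enr_rows.append({**base_enr, "start_date": index_date - 97 * DAY, "end_date": enr_end})
        else:
            enr_rows.append({**base_enr, "start_date": enr_start, "end_date": enr_end})

        # kidney-cancer diagnosis claims (two, >= 30 days apart)
        med_rows.append({"patient_id": pid, "date": index_date - 14 * DAY,
                         "code": kidney_code, "kind": "dx"})
        if fault != "single_dx":
            med_rows.append({"patient_id": pid, "date": index_date + 31 * DAY,
                             "code": kidney_code, "kind": "dx"})

        # baseline comorbidity / metastasis / nephrectomy claims
        for name, cs in study.comorbidity.items():
            if cov.get(name):
                med_rows.append({"patient_id": pid, "date": index_date - 60 * DAY,
                                 "code": cs.prefixes[0], "kind": "dx"})
        for site, cs in study.metastasis.items():
            if cov.get(f"met_{site}"):
                med_rows.append({"patient_id": pid, "date": index_date - 40 * DAY,
                                 "code": cs.prefixes[0], "kind": "dx"})
        if cov.get("nephrectomy"):
            med_rows.append({"patient_id": pid, "date": index_date - 100 * DAY,
                             "code": study.nephrectomy_procedures.prefixes[0],
                             "kind": "proc"})
        if fault == "other_primary":
            code = study.other_primary["breast"].prefixes[0]
            for off in (100, 50):
                med_rows.append({"patient_id": pid, "date": index_date - off * DAY,
                                 "code": code, "kind": "dx"})
        if fault == "tcc":
            drug_rows.append({"patient_id": pid, "date": index_date + 60 * DAY,
                              "agent": config_tcc_agent(study), "days_supply": np.nan,
                              "source": "administration"})
        if fault == "five_day":
            conflict = next(a for a in decoy_pool if a not in (agent,))
            drug_rows.append({"patient_id": pid, "date": index_date + 3 * DAY,
                              "agent": conflict, "days_supply": 30.0,
                              "source": "pharmacy"})
        if replacement:
            decoy = next(a for a in decoy_pool if a != agent)
            drug_rows.append({"patient_id": pid, "date": index_date - 20 * DAY,
                              "agent": decoy, "days_supply": 30.0,
                              "source": "pharmacy"})

        # first-line regimen
        dur1 = _duration_days(rng, agent, config)
        claims1, end1 = _realize_regimen(
            rng, agent, index_date, dur1, enr_end, config, study
        )
        if replacement and sum(c["agent"] != IFN_ALFA for c in claims1) < 2:
            # a one-fill regimen cannot absorb the replacement rule; drop decoy
            drug_rows.pop()
            replacement = False
        for c in claims1:
            drug_rows.append({"patient_id": pid, **c})

        # second line
        line2_agent = None
        line2_start = None
        if end1 is not None and fault is None and rng.random() < config.switch_prob:
            if agent != COMBINATION_AGENT and rng.random() < config.restart_frac:
                gap = study.params.gap_days + 1 + int(
                    round(rng.exponential(config.restart_extra_gap_mean_days))
                )
                start2 = end1 + gap * DAY
                agent2 = agent
            else:
                delay = int(round(rng.exponential(config.switch_delay_mean_days)))
                start2 = max(end1 + delay * DAY, index_date + 31 * DAY)
                mix = {
                    a: w for a, w in config.second_line_mix.items()
                    if a not in (agent, BEVACIZUMAB if agent == COMBINATION_AGENT else agent)
                }
                agent2 = _weighted_choice(rng, mix)
            if start2 <= enr_end:
                dur2 = max(
                    1,
                    int(round(rng.exponential(
                        config.second_line_median_months * DAYS_PER_MONTH / LN2
                    ))),
                )
                claims2, end2 = _realize_regimen(
                    rng, agent2, start2, dur2, enr_end, config, study
                )
                if claims2:
                    for c in claims2:
                        drug_rows.append({"patient_id": pid, **c})
                    line2_agent = agent2
                    line2_start = start2

        # adverse events
        ae_med, ae_truth = generate_ae_history(
            rng, index_date, enr_end, drug_class, config, study
        )
        for m in ae_med:
            med_rows.append({"patient_id": pid, **m})
        for t in ae_truth:
            ae_truth_rows.append({"patient_id": pid, **t})

        truth_rows.append(
            {
                "patient_id": pid,
                "eligible": fault is None,
                "fault": fault,
                "index_date": index_date,
                "index_agent": agent,
                "drug_class": drug_class,
                "route": route,
                "index_year": year,
                "line1_end": end1,
                "line2_agent": line2_agent,
                "line2_start": line2_start,
                "tt2t_days": (
                    int((line2_start - index_date).days) if line2_start is not None else None
                ),
                "enrollment_end": enr_end,
                "age": age,
                "assignment_logit": logit,
                "index_replaced": replacement,
                **{k: cov[k] for k in config.covariate_prevalence},
                "sex": cov["sex"],
                "dcci_true": _true_dcci(cov),
            }
        )

    from .claims_model import ENROLLMENT_COLUMNS

    enrollment = pd.DataFrame(enr_rows)
    enrollment["birth_year"] = enrollment["birth_year"].astype("Int64")
    enrollment = enrollment[ENROLLMENT_COLUMNS]
    medical = pd.DataFrame(med_rows)
    medical["claim_id"] = np.arange(len(medical))
    medical = medical[["patient_id", "date", "claim_id", "code", "kind"]]
    medical = medical.sort_values(["patient_id", "date", "claim_id"]).reset_index(drop=True)
    drug = pd.DataFrame(drug_rows).sort_values(["patient_id", "date"]).reset_index(drop=True)
    enrollment = enrollment.sort_values(["patient_id", "start_date"]).reset_index(drop=True)
    for col in ("start_date", "end_date"):
        enrollment[col] = pd.to_datetime(enrollment[col])
    bundle = ClaimsBundle(enrollment=enrollment, medical=medical, drug=drug)
    truth = GroundTruth(
        patients=pd.DataFrame(truth_rows), ae=pd.DataFrame(ae_truth_rows)
    )
    return bundle, truth


def _true_dcci(cov: dict[str, Any]) -> int:
    weights = {"diabetes": 1, "ckd": 2, "liver_disease": 1, "copd": 1, "chf": 1}
    return sum(w for name, w in weights.items() if cov.get(name))


def config_tcc_agent(study: StudyConfig) -> str:
    return study.tcc_agents[0] if study.tcc_agents else "gemcitabine"


def simulate_cohort_covariates(
    config: SimConfig, n: int | None = None, study: StudyConfig | None = None
) -> pd.DataFrame:
    """Fast path: covariates + class assignment only, no claims realization.

    Uses the same per-patient random streams and assignment model as
    :func:`generate`, so coefficient-recovery studies over many
    replicates need not pay for claims emission.
    """
    config.validate()
    study = study or load_study_config()
    n = n or config.n_patients
    years = sorted(config.index_year_weights)
    yw = np.array([config.index_year_weights[y] for y in years], dtype=float)
    yw = yw / yw.sum()
    rows = []
    for i in range(n):
        rng = patient_rng(config.seed, i)
        year = int(years[rng.choice(len(years), p=yw)])
        y0 = pd.Timestamp(year=year, month=1, day=1)
        ndays = int((pd.Timestamp(year=year + 1, month=1, day=1) - y0).days)
        _ = rng.integers(0, ndays)  # index-day draw, kept for stream parity
        cov = draw_covariates(rng, config)
        agent, logit = assign_treatment(rng, cov, year, config)
        cls, route = study.catalog.classify_agent(agent)
        rows.append(
            {
                "patient_id": f"P{i:06d}", "index_year": year,
                "age_at_index": cov["age"], "sex": cov["sex"],
                "employment": cov["employment"],
                "insurance_type": cov["insurance_type"],
                "drug_class": cls.value, "route": route.value,
                "index_agent": agent, "assignment_logit": logit,
                "dcci": _true_dcci(cov),
                **{k: cov[k] for k in config.covariate_prevalence},
            }
        )
    return pd.DataFrame(rows)
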