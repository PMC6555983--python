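#!/usr/bin/env python
"""Washout-adjusted AE incidence per 100 person-years and onset latency.

For each adverse event, patients with a matching claim inside the
pre-index washout (365 days for chronic conditions, 30 otherwise) are
removed from numerator and denominator; person-time runs from index to
first onset or to 30 days past the end of first-line treatment, capped
at enrollment end.  Rates carry exact (Garwood) Poisson 95% CIs.
"""

from pathlib import Path

import pandas as pd

from mrcc_claims.ae_incidence import (
    build_ae_observations,
    incidence_table,
    latency_table,
)
from mrcc_claims.claims_model import read_claims_bundle
from mrcc_claims.config import load_study_config

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    study = load_study_config()
    bundle = read_claims_bundle(
        ROOT / "scratch" / "bundle", study.catalog, extra_agents=study.tcc_agents
    )
    cohort = pd.read_csv(
        RESULTS / "cohort.csv",
        parse_dates=["index_date", "enrollment_end", "followup_end"],
    )
    episodes = pd.read_csv(
        RESULTS / "episodes.csv",
        parse_dates=["start_date", "end_date", "coverage_end"],
    )
    obs = build_ae_observations(cohort, episodes, bundle, study)
    ir = incidence_table(obs, cohort)
    lat = latency_table(obs, cohort)
    ir.to_csv(RESULTS / "ae_incidence.csv", index=False)
    lat.to_csv(RESULTS / "ae_latency.csv", index=False)

    top = (
        ir[ir["stratum"] == "all"]
        .sort_values("ir_per_100py", ascending=False)
        .head(5)[["ae_name", "n_events", "person_years", "ir_per_100py",
                  "ci_low", "ci_high"]]
    )
    print("most frequent treatment-emergent AEs (per 100 PY, all patients):")
    print(top.to_string(index=False, float_format=lambda v: f"{v:.1f}"))


if __name__ == "__main__":
    main()
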