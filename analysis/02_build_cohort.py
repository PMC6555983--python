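#!/usr/bin/env python
"""Apply the eligibility cascade to the simulated bundle.

Reads scratch/bundle/ (run 01_simulate.py first), applies the inclusion
criteria (>=2 kidney-cancer dx claims >=30 days apart, qualifying
first-line index claim, age >=18, 180-day continuous enrollment both
sides of index) and the TCC / other-primary exclusions, and writes the
cohort and the attrition report to results/.
"""

from pathlib import Path

from mrcc_claims.claims_model import read_claims_bundle
from mrcc_claims.cohort_builder import build_cohort
from mrcc_claims.config import load_study_config

ROOT = Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"
RESULTS = ROOT / "results"


def main() -> None:
    study = load_study_config()
    bundle = read_claims_bundle(BUNDLE, study.catalog, extra_agents=study.tcc_agents)
    cohort, attrition = build_cohort(bundle, study)
    RESULTS.mkdir(exist_ok=True)
    cohort.to_csv(RESULTS / "cohort.csv", index=False)
    attrition.to_csv(RESULTS / "attrition.csv", index=False)
    print(attrition.to_string(index=False))
    print(f"\ncohort: {len(cohort)} patients; "
          f"{(cohort['drug_class'] == 'TK_VEGF').mean():.0%} TK/VEGF, "
          f"{(cohort['route'] == 'ORAL').mean():.0%} oral")


if __name__ == "__main__":
    main()
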