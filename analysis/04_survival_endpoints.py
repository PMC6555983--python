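#!/usr/bin/env python
"""Kaplan-Meier medians for 1L duration and time to second line.

Event/censor rules follow the claims conventions: duration events at
switch or at discontinuation >90 days before enrollment end (censored
at enrollment end otherwise); TT2T censoring at the earlier of episode
end and enrollment end.  Medians are reported in months (days/30.4375)
by drug class, route and agent.
"""

from pathlib import Path

import pandas as pd

from mrcc_claims.survival import endpoint_summary_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    events = pd.read_csv(RESULTS / "events.csv")
    cohort = pd.read_csv(RESULTS / "cohort.csv")
    km = endpoint_summary_table(events, cohort)
    km.to_csv(RESULTS / "km_summary.csv", index=False)
    show = km[km["stratum"].isin(["all", "class", "route"])]
    print(show.to_string(index=False, float_format=lambda v: f"{v:.1f}"))


if __name__ == "__main__":
    main()
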