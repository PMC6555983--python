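#!/usr/bin/env python
"""Annual shares of first-line initiation by class, route and agent.

Route and agent shares sum to 100% per year; the TK/VEGF + mTOR class
shares may fall short of 100% because IL-2 initiators stay in the
denominator.  Writes the tidy trend table (and a line plot if
matplotlib is available).
"""

from pathlib import Path

import pandas as pd

from mrcc_claims.trends import annual_shares

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    cohort = pd.read_csv(RESULTS / "cohort.csv")
    trend = annual_shares(cohort)
    trend.to_csv(RESULTS / "trend.csv", index=False)
    wide = (
        trend[trend["category"] == "class"]
        .pivot(index="year", columns="level", values="percent")
        .round(1)
    )
    print("1L initiation share by drug class (%):")
    print(wide.to_string())
    try:
        from mrcc_claims.trends import plot_trends

        plot_trends(trend, ROOT / "scratch" / "trend.png")
        print("plot -> scratch/trend.png")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
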