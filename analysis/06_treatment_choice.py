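#!/usr/bin/env python
"""Predictors of first-line treatment choice.

Univariate screen (Welch t / chi-square / Fisher, P < 0.2 gate) followed
by multivariate logistic regression for two outcomes: mTOR- vs
TK/VEGF-class therapy, and IV vs oral administration.  Age, sex and
index year are forced into both models; odds ratios carry Wald 95% CIs.
"""

from pathlib import Path

import pandas as pd

from mrcc_claims.predictors import SeparationError, fit_choice_model, univariate_screen

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    cohort = pd.read_csv(RESULTS / "cohort.csv")
    for outcome in ("class", "route"):
        screen = univariate_screen(cohort, outcome)
        screen.to_csv(RESULTS / f"screen_{outcome}.csv", index=False)
        selected = screen.loc[screen["selected"], "covariate"].tolist()
        try:
            ors = fit_choice_model(cohort, outcome, selected)
        except SeparationError as exc:
            print(f"[{outcome}] model degenerate: {exc}")
            continue
        ors.to_csv(RESULTS / f"odds_ratios_{outcome}.csv", index=False)
        sig = ors[ors["p_value"] < 0.05]
        label = "mTOR vs TK/VEGF" if outcome == "class" else "IV vs oral"
        print(f"\nsignificant predictors ({label}):")
        print(sig[["term", "odds_ratio", "ci_low", "ci_high", "p_value"]]
              .to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
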