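"""Annual shares of 1L treatment initiation by class, route and agent.

Year is the calendar year of the index date.  Route and agent shares sum
to 100% within each populated year; the TK/VEGF vs mTOR class shares may
sum to less than 100% because IL-2 initiators are counted in the year's
denominator but belong to neither class.
"""

from __future__ import annotations

import logging

import pandas as pd

log = logging.getLogger(__name__)


def annual_shares(cohort: pd.DataFrame) -> pd.DataFrame:
    """Tidy trend table: year, category ('class'|'route'|'agent'), level,
    count, denominator, percent."""
    if cohort.empty:
        return pd.DataFrame(
            columns=["year", "category", "level", "count", "denominator", "percent"]
        )
    rows = []
    for year, grp in cohort.groupby("index_year", sort=True):
        denom = len(grp)
        if denom == 0:  # pragma: no cover - groupby never yields empty groups
            log.info("year %s has no patients; row omitted", year)
            continue
        for category, col, keep in (
            ("class", "drug_class", ("TK_VEGF", "MTOR")),
            ("route", "route", None),
            ("agent", "index_agent", None),
        ):
            counts = grp[col].value_counts()
            levels = keep if keep is not None else counts.index
            for level in levels:
                c = int(counts.get(level, 0))
                rows.append(
                    {
                        "year": int(year),
                        "category": category,
                        "level": str(level),
                        "count": c,
                        "denominator": denom,
                        "percent": 100.0 * c / denom,
                    }
                )
    return pd.DataFrame(rows)


def plot_trends(trend: pd.DataFrame, path) -> None:
    """Line plot of class/route shares by year (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, category in zip(axes, ("class", "route")):
        sub = trend[trend["category"] == category]
        for level, grp in sub.groupby("level"):
            ax.plot(grp["year"], grp["percent"], marker="o", label=level)
        ax.set_title(f"1L initiation share by {category}")
        ax.set_xlabel("index year")
        ax.set_ylabel("% of initiators")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
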