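"""Predictors of 1L treatment choice: univariate screen + logistic model.

The screen compares baseline covariates between outcome groups (mTOR vs
TK/VEGF inhibitor class, or IV vs oral route) with a Welch t test for
continuous variables and a chi-square test for categorical ones,
switching to Fisher's exact test for 2x2 tables with any expected cell
below 5.  Covariates passing P < 0.2 — plus age, sex and index year,
which are always forced in — enter a multivariate logistic regression.
Odds ratios are exponentiated coefficients with Wald 95% CIs.

Reference levels: TK/VEGF class and oral route are the reference
outcomes; index year 2015, sex M, employment 'retiree' and commercial
insurance are reference covariate levels.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

FORCED_COVARIATES = ("age_at_index", "sex", "index_year")

#: covariate -> measurement type used by the default screen
DEFAULT_COVARIATES: dict[str, str] = {
    "age_at_index": "continuous",
    "sex": "categorical",
    "index_year": "categorical",
    "employment": "categorical",
    "insurance_type": "categorical",
    "dcci": "continuous",
    "diabetes": "categorical",
    "ckd": "categorical",
    "liver_disease": "categorical",
    "copd": "categorical",
    "chf": "categorical",
    "met_lung": "categorical",
    "met_liver": "categorical",
    "met_brain": "categorical",
    "met_bone": "categorical",
    "met_other": "categorical",
    "nephrectomy": "categorical",
}

REFERENCE_LEVELS = {
    "index_year": 2015,
    "sex": "M",
    "employment": "retiree",
    "insurance_type": "commercial",
}


class SeparationError(RuntimeError):
    """The logistic fit is degenerate (perfect separation or one outcome)."""


def outcome_vector(cohort: pd.DataFrame, outcome: str) -> pd.Series:
    """Binary outcome: mTOR (vs TK/VEGF, IL-2 dropped) or IV (vs oral)."""
    if outcome == "class":
        sub = cohort[cohort["drug_class"].isin(["TK_VEGF", "MTOR"])]
        return (sub["drug_class"] == "MTOR").astype(int)
    if outcome == "route":
        return (cohort["route"] == "IV").astype(int)
    raise ValueError(f"outcome must be 'class' or 'route', got {outcome!r}")


def _categorical_test(x: pd.Series, y: pd.Series) -> tuple[str, float]:
    table = pd.crosstab(x, y).to_numpy()
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return "chi2", 1.0  # constant covariate (or outcome) carries no signal
    expected = stats.contingency.expected_freq(table)
    if table.shape == (2, 2) and (expected < 5).any():
        return "fisher", float(stats.fisher_exact(table)[1])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chi2", float(p)


def univariate_screen(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: dict[str, str] | None = None,
    alpha: float = 0.2,
) -> pd.DataFrame:
    """Per-covariate test, P value, and selection flag (P < alpha or forced)."""
    covariates = covariates or {
        k: v for k, v in DEFAULT_COVARIATES.items() if k in cohort.columns
    }
    y = outcome_vector(cohort, outcome)
    data = cohort.loc[y.index]
    rows = []
    for cov, kind in covariates.items():
        x = data[cov]
        if kind == "continuous":
            g0 = x[y == 0].astype(float).dropna()
            g1 = x[y == 1].astype(float).dropna()
            if g0.nunique() <= 1 and g1.nunique() <= 1 and g0.mean() == g1.mean():
                test, p = "t", 1.0
            else:
                test = "t"
                p = float(stats.ttest_ind(g0, g1, equal_var=False).pvalue)
        else:
            test, p = _categorical_test(x, y)
        forced = cov in FORCED_COVARIATES
        rows.append(
            {
                "covariate": cov,
                "test_used": test,
                "p_value": p,
                "forced": forced,
                "selected": bool(p < alpha or forced),
            }
        )
    return pd.DataFrame(rows)


def design_matrix(
    data: pd.DataFrame, covariates: list[str], covariate_types: dict[str, str]
) -> pd.DataFrame:
    """Encode covariates: continuous as-is, categoricals dummy-coded
    against the documented reference level (first observed level otherwise)."""
    cols = {}
    for cov in covariates:
        x = data[cov]
        if covariate_types.get(cov, "categorical") == "continuous":
            cols[cov] = x.astype(float)
        elif x.dropna().nunique() <= 2 and set(x.dropna().unique()) <= {0, 1, True, False}:
            cols[cov] = x.astype(int)
        else:
            ref = REFERENCE_LEVELS.get(cov)
            levels = sorted(x.dropna().unique(), key=str)
            if ref not in levels:
                ref = levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{cov}[{lev}]"] = (x == lev).astype(int)
    X = pd.DataFrame(cols, index=data.index)
    return sm.add_constant(X, has_constant="add")


def fit_choice_model(
    cohort: pd.DataFrame,
    outcome: str,
    selected_covariates: list[str] | None = None,
    covariate_types: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Multivariate logistic fit; returns the OR table (forest-plot-ready).

    When ``selected_covariates`` is None, runs the screen and keeps the
    selected set.  Raises :class:`SeparationError` on degenerate fits
    rather than returning silently unstable estimates.
    """
    covariate_types = covariate_types or DEFAULT_COVARIATES
    if selected_covariates is None:
        screen = univariate_screen(cohort, outcome)
        selected_covariates = screen.loc[screen["selected"], "covariate"].tolist()
    for f in FORCED_COVARIATES:
        if f in cohort.columns and f not in selected_covariates:
            selected_covariates.append(f)

    y = outcome_vector(cohort, outcome)
    if y.nunique() < 2:
        raise SeparationError("outcome has a single level in this cohort")
    data = cohort.loc[y.index]
    X = design_matrix(data, selected_covariates, covariate_types)
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        X = X.loc[:, ~X.T.duplicated()]  # drop aliased dummies
    try:
        with warnings.catch_warnings():
            # degenerate fits are re-raised as SeparationError below
            warnings.simplefilter("ignore")
            fit = sm.Logit(y.to_numpy(), X.astype(float)).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit did not converge (possible separation)")
    if np.abs(fit.params).max() > 15:
        raise SeparationError(
            "implausibly large coefficient; quasi-separation suspected"
        )
    ci = fit.conf_int()
    out = pd.DataFrame(
        {
            "term": X.columns,
            "coef": fit.params.to_numpy(),
            "odds_ratio": np.exp(fit.params.to_numpy()),
            "ci_low": np.exp(ci[0].to_numpy()),
            "ci_high": np.exp(ci[1].to_numpy()),
            "p_value": fit.pvalues.to_numpy(),
        }
    )
    return out[out["term"] != "const"].reset_index(drop=True)
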