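"""Cohort-level regressions: baseline gait vs POMA scores and fall counts.

Three model families, mirroring a concurrent/predictive validation design:

* univariate ordinary least squares of a POMA sub-score (gait or balance)
  on each gait variable;
* univariate Poisson regression (log link) of the fall count on each gait
  variable, with log observation-days as an exposure offset so coefficients
  describe fall *rates*;
* a multivariate Poisson model whose predictors are the univariately
  significant variables, de-duplicated among highly correlated pairs by
  keeping the variable with the higher univariate pseudo-R².

Pseudo-R² for Poisson fits is deviance-based, 1 − D_res/D_null, with an
adjusted variant penalising by predictor count:
adj = 1 − (D_res/(n−k−1)) / (D_null/(n−1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import FEATURE_NAMES

ALPHA_DEFAULT = 0.05
COLLINEARITY_R_DEFAULT = 0.8


@dataclass
class RegressionResult:
    """One fitted association model in tidy form."""

    outcome: str
    predictors: List[str]
    model_type: str  # "linear" or "poisson"
    params: Dict[str, float] = field(default_factory=dict)
    bse: Dict[str, float] = field(default_factory=dict)
    pvalues: Dict[str, float] = field(default_factory=dict)
    r2: Optional[float] = None
    adjusted_r2: Optional[float] = None
    n: int = 0
    converged: bool = True
    note: str = ""

    def to_row(self) -> dict:
        row = {
            "outcome": self.outcome,
            "predictors": "+".join(self.predictors) if self.predictors else "(none)",
            "model_type": self.model_type,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "n": self.n,
            "converged": self.converged,
            "note": self.note,
        }
        for name in ["const"] + self.predictors:
            if name in self.params:
                row[f"coef_{name}"] = self.params[name]
                row[f"se_{name}"] = self.bse[name]
                row[f"p_{name}"] = self.pvalues[name]
        return row


def _complete(records: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    return records.dropna(subset=list(cols))


def univariate_linear(records: pd.DataFrame, feature: str, outcome: str) -> RegressionResult:
    """OLS of a POMA sub-score on one gait variable plus an intercept."""
    df = _complete(records, [feature, outcome])
    n = len(df)
    if n < 3:
        raise ValueError(f"need >=3 complete records, have {n}")
    x = df[feature].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"feature {feature!r} has zero variance (degenerate design)")
    X = sm.add_constant(pd.DataFrame({feature: x}))
    y = df[outcome].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    # constant outcome: define R^2 = 0 (no variance to explain)
    degenerate = np.ptp(y) == 0
    return RegressionResult(
        outcome=outcome,
        predictors=[feature],
        model_type="linear",
        params=dict(fit.params),
        bse=dict(fit.bse),
        pvalues=dict(fit.pvalues),
        r2=0.0 if degenerate else float(fit.rsquared),
        adjusted_r2=0.0 if degenerate else float(fit.rsquared_adj),
        n=n,
    )


def _poisson_fit(df: pd.DataFrame, predictors: Sequence[str], outcome_col: str = "n_falls"):
    y = df[outcome_col].to_numpy(dtype=float)
    offset = np.log(df["exposure_days"].to_numpy(dtype=float))
    X = sm.add_constant(df[list(predictors)].astype(float)) if predictors else pd.DataFrame(
        {"const": np.ones(len(df))}, index=df.index
    )
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
    return model.fit()


def pseudo_r2(fit, null_deviance: float, n: int, k: int) -> Tuple[float, float]:
    """Deviance pseudo-R² and its df-penalised adjustment for a Poisson fit."""
    if null_deviance <= 0:
        raise ValueError("null deviance is zero; pseudo-R² undefined")
    r2 = 1.0 - fit.deviance / null_deviance
    if n - k - 1 <= 0:
        return float(r2), float("nan")
    adj = 1.0 - (fit.deviance / (n - k - 1)) / (null_deviance / (n - 1))
    return float(r2), float(adj)


def univariate_poisson(records: pd.DataFrame, feature: str) -> RegressionResult:
    """Log-link Poisson of fall counts on one gait variable with a
    log-exposure offset; Wald (two-sided) p-value for the coefficient."""
    df = _complete(records, [feature, "n_falls", "exposure_days"])
    n = len(df)
    if n < 3:
        raise ValueError(f"need >=3 complete records, have {n}")
    result = RegressionResult(outcome="n_falls", predictors=[feature], model_type="poisson", n=n)
    try:
        fit = _poisson_fit(df, [feature])
        null_fit = _poisson_fit(df, [])
        result.params = dict(fit.params)
        result.bse = dict(fit.bse)
        result.pvalues = dict(fit.pvalues)
        result.r2, result.adjusted_r2 = pseudo_r2(fit, null_fit.deviance, n, 1)
        result.converged = bool(fit.converged)
    except Exception as exc:  # non-convergence reported, not silently dropped
        result.converged = False
        result.note = f"fit failed: {exc}"
    return result


def multivariate_poisson(records: pd.DataFrame, predictors: Sequence[str]) -> RegressionResult:
    """Poisson fall-rate model on a given predictor set (with offset)."""
    cols = list(predictors) + ["n_falls", "exposure_days"]
    df = _complete(records, cols)
    n = len(df)
    result = RegressionResult(outcome="n_falls", predictors=list(predictors), model_type="poisson", n=n)
    if not predictors:
        result.note = "no significant predictors; empty model"
        return result
    fit = _poisson_fit(df, predictors)
    null_fit = _poisson_fit(df, [])
    result.params = dict(fit.params)
    result.bse = dict(fit.bse)
    result.pvalues = dict(fit.pvalues)
    result.r2, result.adjusted_r2 = pseudo_r2(fit, null_fit.deviance, n, len(predictors))
    result.converged = bool(fit.converged)
    return result


def select_predictors(
    records: pd.DataFrame,
    univariate_results: Dict[str, RegressionResult],
    alpha: float = ALPHA_DEFAULT,
    collinearity_r: float = COLLINEARITY_R_DEFAULT,
) -> List[str]:
    """Variable-selection rule for the multivariate fall model.

    Keep features whose univariate Poisson p-value is below ``alpha``; among
    any pair with |Pearson r| above ``collinearity_r``, keep only the one
    with the higher univariate pseudo-R².
    """
    significant = [
        f
        for f in FEATURE_NAMES
        if f in univariate_results
        and univariate_results[f].converged
        and univariate_results[f].pvalues.get(f, 1.0) < alpha
    ]
    if len(significant) < 2:
        return significant
    corr = records[significant].astype(float).corr().abs()
    # greedy: strongest association first, drop anything collinear with a keeper
    ranked = sorted(significant, key=lambda f: univariate_results[f].r2 or 0.0, reverse=True)
    kept: List[str] = []
    for f in ranked:
        if all(corr.loc[f, g] <= collinearity_r for g in kept):
            kept.append(f)
    return [f for f in FEATURE_NAMES if f in kept]


def build_multivariate(
    records: pd.DataFrame,
    univariate_results: Dict[str, RegressionResult],
    alpha: float = ALPHA_DEFAULT,
    collinearity_r: float = COLLINEARITY_R_DEFAULT,
) -> RegressionResult:
    """Apply the selection rule and fit the multivariate Poisson fall model."""
    predictors = select_predictors(records, univariate_results, alpha=alpha, collinearity_r=collinearity_r)
    return multivariate_poisson(records, predictors)


def run_all_regressions(
    records: pd.DataFrame,
    features: Sequence[str] = FEATURE_NAMES,
    alpha: float = ALPHA_DEFAULT,
    collinearity_r: float = COLLINEARITY_R_DEFAULT,
) -> Dict[str, pd.DataFrame]:
    """The full analysis battery as four tidy tables.

    Keys: ``linear_poma_gait``, ``linear_poma_balance``, ``poisson_falls``
    (univariate, one row per feature) and ``poisson_falls_multivariate``.
    """
    out: Dict[str, pd.DataFrame] = {}
    for outcome in ("poma_gait", "poma_balance"):
        rows = []
        for f in features:
            try:
                rows.append(univariate_linear(records, f, outcome).to_row())
            except ValueError as exc:
                rows.append({"outcome": outcome, "predictors": f, "model_type": "linear", "note": str(exc)})
        out[f"linear_{outcome}"] = pd.DataFrame(rows)
    uni: Dict[str, RegressionResult] = {}
    rows = []
    for f in features:
        try:
            res = univariate_poisson(records, f)
            uni[f] = res
            rows.append(res.to_row())
        except ValueError as exc:
            rows.append({"outcome": "n_falls", "predictors": f, "model_type": "poisson", "note": str(exc)})
    out["poisson_falls"] = pd.DataFrame(rows)
    multi = build_multivariate(records, uni, alpha=alpha, collinearity_r=collinearity_r)
    out["poisson_falls_multivariate"] = pd.DataFrame([multi.to_row()])
    return out
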