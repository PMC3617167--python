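"""Correlation and regression layer for the cohort analyses.

Pearson correlation matrices with t-based p values, partial correlations
controlling for age, ordinary least-squares fits (through statsmodels)
with the partial-regression residual pairs used for added-variable plots,
and reconstruction of R-squared directly from a correlation matrix so
that regressions can be reproduced from published summary moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CorrelationResult",
    "RegressionFit",
    "correlation_matrix",
    "partial_correlation",
    "ols_fit",
    "r2_from_correlations",
]


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationResult:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: int


@dataclass
class RegressionFit:
    """OLS fit summary with added-variable (partial-regression) pairs."""

    response: str
    predictors: list[str]
    params: pd.Series  # unstandardized, incl. intercept
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    standardized: pd.Series  # beta weights, predictors only
    r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    residuals: np.ndarray
    partial_regression: dict[str, tuple[np.ndarray, np.ndarray]]
    n: int


def correlation_matrix(cohort: pd.DataFrame, variables: list[str]) -> CorrelationResult:
    """Pairwise Pearson correlations with two-sided p values.

    p values come from the exact t transform ``t = r sqrt((n-2)/(1-r^2))``
    on n-2 degrees of freedom.  A zero-variance variable yields NaN
    entries (flagged by construction).
    """
    X = cohort[variables].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    rdf = pd.DataFrame(r, index=variables, columns=variables)
    pdf = pd.DataFrame(p, index=variables, columns=variables)
    sdf = pdf.map(_stars)
    return CorrelationResult(list(variables), rdf, pdf, sdf, n)


def partial_correlation(
    cohort: pd.DataFrame, x: str, y: str, control: str | list[str]
) -> float:
    """Correlation of x and y after removing the control variable(s).

    Computed as the correlation of the OLS residuals of x and y on the
    controls (plus intercept); for a single control this equals
    ``(r_xy - r_xc r_yc) / sqrt((1-r_xc^2)(1-r_yc^2))``.
    """
    controls = [control] if isinstance(control, str) else list(control)
    if x in controls or y in controls:
        raise ValueError("x or y coincides with a control variable")
    if len(cohort) < len(controls) + 3:
        raise ValueError("too few observations for the partial correlation")
    Z = sm.add_constant(cohort[controls].to_numpy(dtype=float))
    rx = cohort[x].to_numpy(dtype=float) - Z @ np.linalg.lstsq(Z, cohort[x], rcond=None)[0]
    ry = cohort[y].to_numpy(dtype=float) - Z @ np.linalg.lstsq(Z, cohort[y], rcond=None)[0]
    if np.allclose(rx, 0.0) or np.allclose(ry, 0.0):
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def ols_fit(cohort: pd.DataFrame, response: str, predictors: list[str]) -> RegressionFit:
    """OLS with intercept, classical standard errors, and added-variable
    residual pairs for each predictor.

    Raises on rank deficiency, naming the collinear columns.
    """
    y = cohort[response].to_numpy(dtype=float)
    X = cohort[list(predictors)].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify which predictor drops the rank
        bad = []
        for j, name in enumerate(predictors):
            sub = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise ValueError(f"design is rank deficient; collinear predictors: {bad}")

    model = sm.OLS(y, design).fit()
    names = ["intercept"] + list(predictors)
    params = pd.Series(model.params, index=names)
    sd_y = y.std(ddof=1)
    betas = pd.Series(
        {
            p: params[p] * cohort[p].std(ddof=1) / sd_y
            for p in predictors
        }
    )

    partial: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for p_name in predictors:
        others = [q for q in predictors if q != p_name]
        Z = sm.add_constant(cohort[others].to_numpy(dtype=float), has_constant="add")
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        xp = cohort[p_name].to_numpy(dtype=float)
        rx = xp - Z @ np.linalg.lstsq(Z, xp, rcond=None)[0]
        partial[p_name] = (rx, ry)

    return RegressionFit(
        response=response,
        predictors=list(predictors),
        params=params,
        bse=pd.Series(model.bse, index=names),
        tvalues=pd.Series(model.tvalues, index=names),
        pvalues=pd.Series(model.pvalues, index=names),
        standardized=betas,
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        f_pvalue=float(model.f_pvalue),
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        residuals=np.asarray(model.resid),
        partial_regression=partial,
        n=len(y),
    )


def r2_from_correlations(
    corr: pd.DataFrame | np.ndarray,
    response: str | int,
    predictors: list[str] | list[int],
) -> float:
    """R-squared of a regression implied by a correlation matrix alone.

    ``r' R^{-1} r`` for the response-predictor correlation vector r and
    the predictor intercorrelation matrix R.  Exactly equals the OLS
    R-squared on any data set with those sample correlations.
    """
    if isinstance(corr, pd.DataFrame):
        r = corr.loc[predictors, response].to_numpy(dtype=float)
        R = corr.loc[predictors, predictors].to_numpy(dtype=float)
    else:
        corr = np.asarray(corr, dtype=float)
        r = corr[predictors, response]
        R = corr[np.ix_(predictors, predictors)]
    if np.linalg.det(R) == 0 or np.linalg.cond(R) > 1e12:
        raise ValueError("predictor correlation matrix is singular")
    return float(r @ np.linalg.solve(R, r))
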