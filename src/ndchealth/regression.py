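"""Country-level regression models of health engagement.

Three models mirror the analysis design: logistic regression for any mention
of health, and ordinary least squares with heteroscedasticity-robust (HC1)
standard errors for the health engagement score (HES) and the health topic
proportion (HTP); the total health term count is available as a sensitivity
outcome. Estimation is delegated to statsmodels (Logit and OLS with sandwich
covariance); this module supplies the listwise-deletion step, the fixed
covariate set, Wald 95% CIs on the coefficient scale and McFadden's
pseudo-R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "COVARIATE_COLUMNS",
    "RegressionResult",
    "listwise_complete",
    "fit_logistic",
    "fit_ols_robust",
    "mcfadden_pseudo_r2",
]

#: Predictors entering every model, in presentation order.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "log_population",
    "sids",
    "log_gdp_per_capita",
    "democracy",
    "health_expenditure_pct_gdp",
    "coal_rents_pct_gdp",
    "temp_change_weighted",
    "pm25_exposure",
)


@dataclass
class RegressionResult:
    """Fitted coefficients with uncertainties and fit statistics."""

    model: str                      # "logistic" | "ols"
    outcome: str
    params: pd.Series
    bse: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    n_used: int
    r2: float | None = None
    pseudo_r2: float | None = None
    cov_type: str = "nonrobust"
    dropped_iso3: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if ((self.ci_low > self.params) | (self.ci_high < self.params)).any():
            raise ValueError("confidence bounds must bracket the point estimates")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.params,
                "se": self.bse,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        head = (
            f"{self.model.upper()} regression — outcome: {self.outcome} "
            f"(n={self.n_used}, cov={self.cov_type})"
        )
        fit = (
            f"pseudo-R2 (McFadden): {self.pseudo_r2:.3f}"
            if self.pseudo_r2 is not None
            else f"R2: {self.r2:.3f}"
        )
        body = self.to_frame().round(4).to_string()
        return "\n".join([head, "=" * len(head), body, fit])


def listwise_complete(
    records: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: Sequence[str] = COVARIATE_COLUMNS,
    outcome_cols: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Merge covariates and outcomes on ``iso3`` and drop incomplete rows.

    Returns the analysis table and the sorted list of dropped iso3 codes.
    Outcomes may be keyed by ``iso3`` or ``doc_id``.
    """
    out = outcomes.rename(columns={"doc_id": "iso3"}).copy()
    merged = records.merge(out, on="iso3", how="outer")
    check = list(covariates) + list(
        outcome_cols
        if outcome_cols is not None
        else [c for c in out.columns if c != "iso3"]
    )
    missing_cols = [c for c in check if c not in merged.columns]
    if missing_cols:
        raise KeyError(f"analysis columns missing from inputs: {missing_cols}")
    complete = merged.dropna(subset=check)
    dropped = sorted(set(merged["iso3"]) - set(complete["iso3"]))
    if len(complete) < 2:
        raise ValueError("fewer than 2 complete rows after listwise deletion")
    return complete.reset_index(drop=True), dropped


def _design(data: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    X = sm.add_constant(data.loc[:, list(covariates)].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns that do not add rank
        culprits = []
        base: list[str] = []
        for col in X.columns:
            trial = base + [col]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == len(base):
                culprits.append(col)
            else:
                base = trial
        raise ValueError(f"design matrix is rank deficient; collinear columns: {culprits}")
    return X


def fit_logistic(
    data: pd.DataFrame,
    outcome: str = "any_mention",
    covariates: Sequence[str] = COVARIATE_COLUMNS,
    robust: bool = False,
) -> RegressionResult:
    """Maximum-likelihood logistic regression with Wald 95% CIs.

    Conventional observed-information standard errors by default;
    ``robust=True`` switches to HC1 sandwich standard errors.
    """
    y = data[outcome].astype(float)
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    if len(classes) < 2:
        raise ValueError(f"outcome {outcome!r} has a single class; cannot fit")
    X = _design(data, covariates)
    model = sm.Logit(y, X)
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        try:
            res = model.fit(disp=False, cov_type="HC1" if robust else "nonrobust")
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise ValueError(f"logistic fit failed: {err}") from err
    separated = any(
        issubclass(w.category, PerfectSeparationWarning) for w in caught
    )
    if separated or not res.mle_retvals.get("converged", True):
        reason = (
            "perfect separation detected: some covariate combination "
            "predicts the outcome exactly"
            if separated
            else "maximum-likelihood estimation did not converge"
        )
        raise ValueError(f"logistic fit failed — {reason}")
    ci = res.conf_int(alpha=0.05)
    return RegressionResult(
        model="logistic",
        outcome=outcome,
        params=res.params,
        bse=res.bse,
        ci_low=ci[0],
        ci_high=ci[1],
        pvalues=res.pvalues,
        n_used=int(res.nobs),
        pseudo_r2=mcfadden_pseudo_r2(res),
        cov_type="HC1" if robust else "ml",
    )


def fit_ols_robust(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = COVARIATE_COLUMNS,
    hc_type: str = "HC1",
) -> RegressionResult:
    """OLS with heteroscedasticity-robust standard errors.

    ``hc_type`` selects the sandwich small-sample correction (HC0–HC3;
    HC1 applies the n/(n−k) factor). Coefficients are identical across
    covariance choices; only the uncertainties differ.
    """
    if hc_type not in ("HC0", "HC1", "HC2", "HC3", "nonrobust"):
        raise ValueError(f"unsupported covariance type {hc_type!r}")
    y = data[outcome].astype(float)
    X = _design(data, covariates)
    res = sm.OLS(y, X).fit(
        cov_type=hc_type if hc_type != "nonrobust" else "nonrobust"
    )
    ci = res.conf_int(alpha=0.05)
    return RegressionResult(
        model="ols",
        outcome=outcome,
        params=res.params,
        bse=res.bse,
        ci_low=ci[0],
        ci_high=ci[1],
        pvalues=res.pvalues,
        n_used=int(res.nobs),
        r2=float(res.rsquared),
        cov_type=hc_type,
    )


def mcfadden_pseudo_r2(fitted) -> float:
    """McFadden's pseudo-R²: 1 − ll_model / ll_null."""
    if fitted.llnull == 0:
        return 0.0
    return float(1.0 - fitted.llf / fitted.llnull)
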