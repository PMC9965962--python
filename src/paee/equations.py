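"""Development of PAEE prediction equations.

Candidate equations regress criterion PAEE (kcal/min) on combinations of
sex, anthropometry, body composition and accelerometer counts per
minute.  Selection follows the study procedure: stepwise multiple
regression (forward with a backward look), variance-inflation-factor
screening of collinear candidates, and a pooled-versus-sex-specific
comparison on goodness of fit (R^2 and RMSE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FittedEquation",
    "SelectionResult",
    "DEFAULT_CANDIDATES",
    "fit_ols",
    "predict",
    "vif",
    "stepwise_select",
    "fit_sex_specific",
    "select_best",
]

# union of the candidate sets considered during development
DEFAULT_CANDIDATES = [
    "age", "sex_code", "weight", "height", "bmi", "ffm", "fm", "cpm",
]

RESPONSE = "paee"


@dataclass
class FittedEquation:
    """A fitted linear PAEE prediction model.

    ``r2_pct`` is the coefficient of determination in percent; ``rmse``
    is the residual standard error ``sqrt(SSE / (n - p - 1))`` in
    kcal/min; ``r`` is the multiple correlation ``sqrt(R2)``.
    """

    predictors: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    r: float
    r2_pct: float
    rmse: float
    n: int
    sex_scope: str = "pooled"  # pooled | male | female
    vif: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)


@dataclass
class SelectionResult:
    chosen: str  # "pooled" or "sex_specific"
    pooled: FittedEquation
    male: FittedEquation | None
    female: FittedEquation | None
    rationale: str

    @property
    def equation(self) -> FittedEquation:
        return self.pooled


def _design(dataset: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    x = dataset[list(predictors)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(dataset)), x])


def fit_ols(
    dataset: pd.DataFrame,
    predictors: list[str],
    response: str = RESPONSE,
    sex_scope: str = "pooled",
) -> FittedEquation:
    """Ordinary least squares fit of ``response`` on ``predictors``.

    R^2 uses the centred total sum of squares; RMSE is the residual
    standard error with ``n - p - 1`` degrees of freedom.
    """
    predictors = list(predictors)
    n = len(dataset)
    if n <= len(predictors) + 1:
        raise ValueError("not enough rows for the requested predictors")
    y = dataset[response].to_numpy(dtype=float)
    x = _design(dataset, predictors)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"rank-deficient design for predictors {predictors}")
    model = sm.OLS(y, x).fit()
    sse = float(model.ssr)
    p = len(predictors)
    r2 = 100.0 * float(model.rsquared) if p else 0.0
    rmse = math.sqrt(sse / (n - p - 1))
    coef = {"intercept": float(model.params[0])}
    pvals = {}
    for j, name in enumerate(predictors, start=1):
        coef[name] = float(model.params[j])
        pvals[name] = float(model.pvalues[j])
    return FittedEquation(
        predictors=predictors,
        coefficients=coef,
        r=math.sqrt(max(r2, 0.0) / 100.0),
        r2_pct=r2,
        rmse=rmse,
        n=n,
        sex_scope=sex_scope,
        vif=vif(dataset, predictors) if p >= 2 else {},
        pvalues=pvals,
    )


def predict(equation: FittedEquation, dataset: pd.DataFrame) -> np.ndarray:
    """Evaluate a fitted equation on new rows."""
    out = np.full(len(dataset), equation.coefficients["intercept"], dtype=float)
    for name in equation.predictors:
        out += equation.coefficients[name] * dataset[name].to_numpy(dtype=float)
    return out


def vif(dataset: pd.DataFrame, predictors: list[str]) -> dict[str, float]:
    """Variance inflation factors via auxiliary regressions.

    ``VIF_j = 1 / (1 - R2_j)`` where ``R2_j`` regresses predictor j on
    the remaining predictors; perfect collinearity yields ``inf``.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    out: dict[str, float] = {}
    for name in predictors:
        others = [p for p in predictors if p != name]
        y = dataset[name].to_numpy(dtype=float)
        x = _design(dataset, others)
        model = sm.OLS(y, x).fit()
        r2 = float(model.rsquared)
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def stepwise_select(
    dataset: pd.DataFrame,
    candidates: list[str] | None = None,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    vif_limit: float = 10.0,
    response: str = RESPONSE,
    sex_scope: str = "pooled",
) -> FittedEquation:
    """Forward stepwise regression with a backward look.

    At each step the candidate with the smallest coefficient p-value
    below ``alpha_enter`` is added (ties broken by candidate-list
    order); after each addition, any included term whose p-value rises
    above ``alpha_remove`` is removed, worst first.  Candidates whose
    VIF against the current model would exceed ``vif_limit`` are barred
    from entry.  If nothing enters, the intercept-only model is
    returned.
    """
    if candidates is None:
        candidates = [c for c in DEFAULT_CANDIDATES if c in dataset.columns]
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate predictors")
    included: list[str] = []
    while True:
        best_name, best_p = None, alpha_enter
        for name in candidates:
            if name in included:
                continue
            trial = included + [name]
            if len(dataset) <= len(trial) + 1:
                continue
            x = _design(dataset, trial)
            if np.linalg.matrix_rank(x) < x.shape[1]:
                continue
            if len(trial) >= 2:
                trial_vif = vif(dataset, trial)
                if trial_vif[name] > vif_limit:
                    continue
            fitted = fit_ols(dataset, trial, response=response)
            p_val = fitted.pvalues[name]
            if math.isnan(p_val):
                continue
            if p_val < best_p:
                best_name, best_p = name, p_val
        if best_name is None:
            break
        included.append(best_name)
        # backward look
        while len(included) > 0:
            fitted = fit_ols(dataset, included, response=response)
            worst = max(included, key=lambda t: fitted.pvalues[t])
            if fitted.pvalues[worst] > alpha_remove and worst != best_name:
                included.remove(worst)
            else:
                break
    if not included:
        y = dataset[response].to_numpy(dtype=float)
        return FittedEquation(
            predictors=[],
            coefficients={"intercept": float(y.mean())},
            r=0.0,
            r2_pct=0.0,
            rmse=float(y.std(ddof=1)),
            n=len(dataset),
            sex_scope=sex_scope,
        )
    return fit_ols(dataset, included, response=response, sex_scope=sex_scope)


def fit_sex_specific(
    dataset: pd.DataFrame,
    predictors: list[str],
    response: str = RESPONSE,
) -> dict[str, FittedEquation]:
    """Independent fits on the male and female subsets."""
    out = {}
    for scope, code in (("male", 1), ("female", 0)):
        subset = dataset[dataset["sex_code"] == code]
        if len(subset) < len(predictors) + 2:
            raise ValueError(f"{scope} subset too small for {predictors}")
        out[scope] = fit_ols(
            subset, predictors, response=response, sex_scope=scope
        )
    return out


def select_best(
    pooled: FittedEquation,
    male: FittedEquation | None = None,
    female: FittedEquation | None = None,
    r2_margin_pct: float = 5.0,
) -> SelectionResult:
    """Prefer the pooled equation unless sex-specific fits clearly win.

    The sex-specific pair is chosen only when it improves R^2 by more
    than ``r2_margin_pct`` percentage points AND lowers RMSE in both
    sexes; otherwise the simpler pooled equation is kept.
    """
    if male is None or female is None:
        return SelectionResult(
            "pooled", pooled, male, female, "single candidate equation"
        )
    r2_gain_male = male.r2_pct - pooled.r2_pct
    r2_gain_female = female.r2_pct - pooled.r2_pct
    better = (
        r2_gain_male > r2_margin_pct
        and r2_gain_female > r2_margin_pct
        and male.rmse < pooled.rmse
        and female.rmse < pooled.rmse
    )
    if better:
        rationale = (
            f"sex-specific fits improve R2 by {r2_gain_male:.1f}/"
            f"{r2_gain_female:.1f} points with lower RMSE in both sexes"
        )
        return SelectionResult("sex_specific", pooled, male, female, rationale)
    rationale = (
        f"sex-specific fits do not improve R2 by more than "
        f"{r2_margin_pct:.0f} points in both sexes "
        f"({r2_gain_male:.1f}/{r2_gain_female:.1f}); pooled equation kept"
    )
    return SelectionResult("pooled", pooled, male, female, rationale)
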