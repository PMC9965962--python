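"""Validation machinery: outlier screen, split, PRESS, Bland-Altman.

Implements the study's validation toolkit: the +-3 SD outlier screen,
the deterministic every-third split into validation and cross-validation
groups, pure error of a fixed equation on an independent group, the
PRESS (predicted residual error sum of squares) leave-one-out statistics
of a final fit, Bland-Altman agreement limits, and the paired t-test
comparing criterion and predicted PAEE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .equations import RESPONSE, FittedEquation, _design, predict

__all__ = [
    "PressResult",
    "ValidationReport",
    "filter_outliers",
    "split_every_third",
    "pure_error",
    "press_statistics",
    "bland_altman",
    "paired_t",
    "validate_equation",
]


@dataclass
class PressResult:
    press: float  # (kcal/min)^2, sum over left-out squared residuals
    press_rmse: float  # sqrt(PRESS/n), kcal/min
    press_r2_pct: float  # 100 * (1 - PRESS/SST)
    n: int
    p: int


@dataclass
class ValidationReport:
    n: int
    mean_criterion: float
    sd_criterion: float
    mean_predicted: float
    sd_predicted: float
    t_statistic: float
    p_value: float
    correlation_r: float
    pure_error: float
    rmse_validation: float
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    notes: list[str] = field(default_factory=list)


def filter_outliers(
    dataset: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass +-3 SD screen over the analysis columns.

    A row is removed when ANY screened column deviates more than three
    standard deviations from that column's mean; means and SDs are
    computed once on the full input (no re-computation after removals).
    Zero-variance columns are skipped with a warning.
    """
    if len(dataset) < 3:
        raise ValueError("outlier screen needs at least 3 rows")
    if columns is None:
        columns = [
            c for c in dataset.columns
            if pd.api.types.is_numeric_dtype(dataset[c])
        ]
    remove = np.zeros(len(dataset), dtype=bool)
    for col in columns:
        values = dataset[col].to_numpy(dtype=float)
        sd = values.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"column {col!r} has zero variance; skipped")
            continue
        z = (values - values.mean()) / sd
        remove |= np.abs(z) > 3.0
    return dataset[~remove].copy(), dataset[remove].copy()


def split_every_third(cohort: pd.DataFrame) -> pd.DataFrame:
    """Assign every third participant within sex to cross-validation.

    Within each sex, participants are listed by ascending age (ties
    broken by participant_id), and 1-based positions 3, 6, 9, ... go to
    the cross-validation group; the remainder form the validation
    group.  The assignment is invariant to the input row order.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    assignment = {}
    for _, group in cohort.groupby("sex_code"):
        ordered = group.sort_values(
            ["age", "participant_id"], kind="mergesort"
        )
        for pos, pid in enumerate(ordered["participant_id"], start=1):
            assignment[pid] = "cross_validation" if pos % 3 == 0 else "validation"
    out = cohort[["participant_id"]].copy()
    out["group"] = out["participant_id"].map(assignment)
    return out


def pure_error(observed, predicted) -> float:
    """Root mean squared prediction error of a fixed equation.

    ``sqrt(sum((observed - predicted)^2) / n)`` -- the denominator is n,
    not a residual degree of freedom, because no parameter was estimated
    on these rows.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("length mismatch")
    if obs.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def press_statistics(
    dataset: pd.DataFrame,
    predictors: list[str],
    response: str = RESPONSE,
) -> PressResult:
    """Leave-one-out PRESS statistics via the hat-matrix closed form.

    The deleted residual of row i is ``e_i / (1 - h_ii)``; rows with
    leverage one are refit explicitly.  ``press_rmse = sqrt(PRESS/n)``
    is commensurable with pure error; ``press_r2 = 100(1 - PRESS/SST)``
    is always at most the fitted R^2.
    """
    predictors = list(predictors)
    n = len(dataset)
    if n <= len(predictors) + 1:
        raise ValueError("not enough rows")
    y = dataset[response].to_numpy(dtype=float)
    x = _design(dataset, predictors)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    q, _ = np.linalg.qr(x)
    hat = np.sum(q * q, axis=1)
    loo = np.empty(n)
    for i in range(n):
        if 1.0 - hat[i] < 1e-10:
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            beta_i, *_ = np.linalg.lstsq(x[mask], y[mask], rcond=None)
            loo[i] = y[i] - x[i] @ beta_i
        else:
            loo[i] = resid[i] / (1.0 - hat[i])
    press = float(np.sum(loo**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return PressResult(
        press=press,
        press_rmse=math.sqrt(press / n),
        press_r2_pct=100.0 * (1.0 - press / sst) if sst > 0 else float("nan"),
        n=n,
        p=len(predictors),
    )


def bland_altman(a, b) -> tuple[float, float, tuple[float, float], pd.DataFrame]:
    """Bland-Altman agreement: bias, SD of differences, 1.96-SD limits.

    Differences are ``a - b``; the returned frame carries the (mean,
    difference) pairs for plotting.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    bias = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    loa = (bias - 1.96 * sd_diff, bias + 1.96 * sd_diff)
    pairs = pd.DataFrame({"mean": (a + b) / 2.0, "difference": diff})
    return bias, sd_diff, loa, pairs


def paired_t(a, b) -> dict[str, float]:
    """Two-sided paired t-test of two measurement series.

    Raises on zero difference variance: with degenerate differences the
    t statistic is undefined and the comparison is meaningless.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    if diff.std(ddof=1) == 0:
        raise ValueError("zero variance of differences; t undefined")
    t_stat, p_val = stats.ttest_rel(a, b)
    return {
        "t": float(t_stat),
        "p": float(p_val),
        "df": a.size - 1,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }


def validate_equation(
    preliminary: FittedEquation,
    cross_group: pd.DataFrame,
    response: str = RESPONSE,
) -> ValidationReport:
    """Assess a fixed preliminary equation on the cross-validation group.

    Combines the paired t-test, the criterion/predicted correlation,
    pure error (compared with the equation's development RMSE) and the
    Bland-Altman agreement of criterion minus predicted PAEE.
    """
    criterion = cross_group[response].to_numpy(dtype=float)
    predicted = predict(preliminary, cross_group)
    notes: list[str] = []
    try:
        t_res = paired_t(criterion, predicted)
        t_stat, p_val = t_res["t"], t_res["p"]
    except ValueError as err:
        notes.append(f"paired t-test degenerate: {err}")
        t_stat, p_val = float("nan"), float("nan")
    if np.std(criterion) > 0 and np.std(predicted) > 0:
        corr = float(np.corrcoef(criterion, predicted)[0, 1])
    else:
        corr = float("nan")
        notes.append("correlation undefined (constant series)")
    pe = pure_error(criterion, predicted)
    bias, sd_diff, (loa_lo, loa_hi), _ = bland_altman(criterion, predicted)
    if preliminary.rmse > 0:
        notes.append(
            f"pure error {pe:.4f} vs development RMSE {preliminary.rmse:.4f} "
            f"(ratio {pe / preliminary.rmse:.3f})"
        )
    return ValidationReport(
        n=len(cross_group),
        mean_criterion=float(criterion.mean()),
        sd_criterion=float(criterion.std(ddof=1)),
        mean_predicted=float(predicted.mean()),
        sd_predicted=float(predicted.std(ddof=1)),
        t_statistic=t_stat,
        p_value=p_val,
        correlation_r=corr,
        pure_error=pe,
        rmse_validation=preliminary.rmse,
        bias=bias,
        sd_diff=sd_diff,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        notes=notes,
    )
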