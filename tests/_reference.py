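"""Independent reference implementations used as test oracles.

These deliberately use different algorithms from the package code
(naive loops, normal equations, explicit refits) so that agreement is a
genuine dual-route check.
"""

from __future__ import annotations

import numpy as np


def nonwear_reference(
    vm: np.ndarray,
    min_bout_min: int = 60,
    max_interruption_min: int = 2,
    spike_tolerance: float = 100.0,
) -> np.ndarray:
    """Minute-by-minute state machine for the non-wear rule.

    A candidate bout starts at a zero minute, extends through zeros,
    spends the interruption budget on sub-tolerance non-zero minutes,
    terminates on a spike or an over-budget interruption, and is trimmed
    to its last zero.  Returns the wear mask (True = wear).
    """
    n = len(vm)
    wear = np.ones(n, dtype=bool)
    i = 0
    while i < n:
        if vm[i] != 0:
            i += 1
            continue
        interruptions = 0
        last_zero = i
        j = i + 1
        while j < n:
            if vm[j] == 0:
                last_zero = j
            elif vm[j] < spike_tolerance and interruptions < max_interruption_min:
                interruptions += 1
            else:
                break
            j += 1
        if last_zero - i + 1 >= min_bout_min:
            wear[i : last_zero + 1] = False
        i = j + 1
    return wear


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients (intercept first) by solving X'X b = X'y directly."""
    design = np.column_stack([np.ones(len(y)), x])
    return np.linalg.solve(design.T @ design, design.T @ y)


def press_by_refitting(x: np.ndarray, y: np.ndarray) -> float:
    """PRESS by explicitly refitting with each row left out."""
    n = len(y)
    design = np.column_stack([np.ones(n), x])
    total = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        beta, *_ = np.linalg.lstsq(design[mask], y[mask], rcond=None)
        total += float((y[i] - design[i] @ beta) ** 2)
    return total


def vif_by_auxiliary(x: np.ndarray) -> np.ndarray:
    """VIFs by explicit auxiliary regressions on raw arrays."""
    p = x.shape[1]
    out = np.empty(p)
    for j in range(p):
        others = np.delete(x, j, axis=1)
        design = np.column_stack([np.ones(len(x)), others])
        beta, *_ = np.linalg.lstsq(design, x[:, j], rcond=None)
        resid = x[:, j] - design @ beta
        sst = ((x[:, j] - x[:, j].mean()) ** 2).sum()
        r2 = 1.0 - (resid**2).sum() / sst
        out[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out
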