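"""Feature reduction: VIF screening and backward elimination.

Tie-breaking is deterministic: among tied candidates the later column in
declared order is removed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ols import RegressionFit, intercept_only_fit, ols_fit

VIF_THRESHOLD = 10.0
ALPHA = 0.05


@dataclass
class ReductionStep:
    removed: str
    criterion: str  # {"VIF", "p-value"}
    value: float
    remaining: list[str]
    metrics_after: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "removed": self.removed,
            "criterion": self.criterion,
            "value": None if math.isinf(self.value) else self.value,
            "value_is_inf": math.isinf(self.value),
            "remaining": self.remaining,
            "metrics_after": self.metrics_after,
        }


@dataclass
class ReductionTrace:
    steps: list[ReductionStep] = field(default_factory=list)

    def removed_features(self) -> list[str]:
        return [s.removed for s in self.steps]

    def to_dict(self) -> list[dict]:
        return [s.to_dict() for s in self.steps]


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 − R²_j).

    R²_j comes from regressing column j on the remaining columns with an
    intercept. Perfect collinearity yields +inf, not an exception.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("VIF needs >= 2 features")
    values = {}
    for j, col in enumerate(cols):
        others = X[[c for c in cols if c != col]]
        fit = ols_fit(others, X[col].to_numpy(dtype=float), force=True)
        r2 = min(fit.r_squared, 1.0)
        values[col] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(values)


def reduce_by_vif(
    X: pd.DataFrame, threshold: float = VIF_THRESHOLD
) -> tuple[pd.DataFrame, ReductionTrace]:
    """Iteratively drop the highest-VIF feature while any VIF ≥ threshold."""
    kept = X.copy()
    trace = ReductionTrace()
    while kept.shape[1] >= 2:
        scores = vif(kept)
        worst_value = scores.max()
        if worst_value < threshold:
            break
        # argmax with later-column tie-break
        worst = [c for c in kept.columns if scores[c] == worst_value][-1]
        kept = kept.drop(columns=[worst])
        trace.steps.append(
            ReductionStep(
                removed=worst,
                criterion="VIF",
                value=float(worst_value),
                remaining=[str(c) for c in kept.columns],
            )
        )
    return kept, trace


def backward_eliminate(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    alpha: float = ALPHA,
) -> tuple[RegressionFit, ReductionTrace]:
    """Drop the largest-p-value feature until every coefficient has p < alpha.

    The intercept is never removed. If every feature is eliminated, an
    intercept-only fit is returned with its flag set.
    """
    kept = X.copy()
    y_arr = np.asarray(y, dtype=float)
    trace = ReductionTrace()
    while kept.shape[1] > 0:
        fit = ols_fit(kept, y_arr)
        pvals = pd.Series(fit.p_values)
        worst_value = pvals.max()
        if worst_value < alpha:
            return fit, trace
        worst = [c for c in kept.columns if fit.p_values[str(c)] == worst_value][-1]
        kept = kept.drop(columns=[worst])
        step = ReductionStep(
            removed=str(worst),
            criterion="p-value",
            value=float(worst_value),
            remaining=[str(c) for c in kept.columns],
        )
        if kept.shape[1] > 0:
            refit = ols_fit(kept, y_arr)
            step.metrics_after = {
                "r_squared": refit.r_squared,
                "adj_r_squared": refit.adj_r_squared,
            }
        trace.steps.append(step)
    fit = intercept_only_fit(y_arr)
    return fit, trace
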