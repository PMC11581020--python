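"""Ordinary least squares fitting with intercept and Student-t inference."""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class InsufficientDofError(ValueError):
    pass


@dataclass
class RegressionFit:
    feature_names: list[str]
    coefficients: dict[str, float]
    intercept: float
    std_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    conf_intervals: dict[str, tuple[float, float]]  # 95%, Student's t at residual df
    r_squared: float
    adj_r_squared: float
    n_obs: int
    k_features: int
    rank_deficient: bool = False
    inference_valid: bool = True
    intercept_only: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "features": self.feature_names,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "std_errors": self.std_errors,
            "t_values": self.t_values,
            "p_values": self.p_values,
            "conf_intervals": {k: list(v) for k, v in self.conf_intervals.items()},
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "n_obs": self.n_obs,
            "k_features": self.k_features,
            "rank_deficient": self.rank_deficient,
            "inference_valid": self.inference_valid,
            "intercept_only": self.intercept_only,
            "notes": self.notes,
        }


def ols_fit(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    force: bool = False,
) -> RegressionFit:
    """Least-squares fit of y on X plus an intercept.

    Rank-deficient designs are solved via the pseudo-inverse (minimum-norm
    coefficients) with a recorded rank warning. Requires n > k + 1 for exact
    inference; pass ``force=True`` to fit anyway (inference flagged invalid).
    """
    X = pd.DataFrame(X)
    names = [str(c) for c in X.columns]
    y_arr = np.asarray(y, dtype=float)
    n, k = X.shape
    if n != len(y_arr):
        raise ValueError(f"X has {n} rows but y has {len(y_arr)}")
    if n <= k + 1 and not force:
        raise InsufficientDofError(
            f"n = {n} observations insufficient for k = {k} features + intercept; "
            "pass force=True to fit without exact inference"
        )

    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.OLS(y_arr, design)
        result = model.fit(method="pinv")
        params = np.asarray(result.params)
        bse = np.asarray(result.bse)
        tvals = np.asarray(result.tvalues)
        pvals = np.asarray(result.pvalues)
        rsquared = float(result.rsquared)
        rsquared_adj = float(result.rsquared_adj)

    rank = np.linalg.matrix_rank(design)
    rank_deficient = rank < design.shape[1]
    notes = []
    if rank_deficient:
        notes.append(
            f"design matrix rank {rank} < {design.shape[1]} columns; "
            "minimum-norm (pseudo-inverse) solution reported"
        )

    df_resid = n - rank
    inference_valid = df_resid > 0
    if df_resid > 0:
        tcrit = stats.t.ppf(0.975, df_resid)
        ci = np.column_stack([params - tcrit * bse, params + tcrit * bse])
    else:
        ci = np.column_stack([np.full(k + 1, np.nan), np.full(k + 1, np.nan)])
        inference_valid = False

    return RegressionFit(
        feature_names=names,
        coefficients={name: float(params[i + 1]) for i, name in enumerate(names)},
        intercept=float(params[0]),
        std_errors={name: float(bse[i + 1]) for i, name in enumerate(names)},
        t_values={name: float(tvals[i + 1]) for i, name in enumerate(names)},
        p_values={name: float(pvals[i + 1]) for i, name in enumerate(names)},
        conf_intervals={name: (float(ci[i + 1, 0]), float(ci[i + 1, 1])) for i, name in enumerate(names)},
        r_squared=rsquared,
        adj_r_squared=rsquared_adj,
        n_obs=n,
        k_features=k,
        rank_deficient=rank_deficient,
        inference_valid=bool(inference_valid),
        intercept_only=(k == 0),
        notes=notes,
    )


def intercept_only_fit(y: pd.Series | np.ndarray) -> RegressionFit:
    y_arr = np.asarray(y, dtype=float)
    fit = ols_fit(pd.DataFrame(index=range(len(y_arr))), y_arr, force=True)
    fit.intercept_only = True
    return fit


def simple_regressions(
    features: pd.DataFrame,
    y: pd.Series | np.ndarray,
    feature_names: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Single-feature OLS per column: Pearson r, R² (= r²), slope, p-value."""
    names = feature_names or [str(c) for c in features.columns]
    y_arr = np.asarray(y, dtype=float)
    rows = []
    for name in names:
        x = features[name]
        fit = ols_fit(x.to_frame(), y_arr)
        r = float(np.corrcoef(np.asarray(x, dtype=float), y_arr)[0, 1])
        rows.append(
            {
                "feature": name,
                "r": r,
                "r_squared": fit.r_squared,
                "slope": fit.coefficients[name],
                "intercept": fit.intercept,
                "p_value": fit.p_values[name],
            }
        )
    return pd.DataFrame(rows)
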