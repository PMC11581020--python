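"""Dependent-variable and feature-matrix transformations."""
from __future__ import annotations

import numpy as np
import pandas as pd


def log_transform(values: pd.Series | np.ndarray, base: float = 10.0) -> pd.Series | np.ndarray:
    """Element-wise logarithm (base 10 by default) of a positive response.

    Downstream R², p-values and feature selection are invariant to the base.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        bad = np.flatnonzero((arr <= 0) | ~np.isfinite(arr))
        names = (
            [str(values.index[i]) for i in bad[:5]]
            if isinstance(values, pd.Series)
            else [str(i) for i in bad[:5]]
        )
        raise ValueError(f"log transform requires positive values; offending rows: {names}")
    out = np.log(arr) / np.log(base)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def standardize(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Scale each column to sample mean 0 and standard deviation 1."""
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=ddof)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"zero-variance column(s): {constant}")
    return (matrix - mu) / sd


def pearson_correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix with unit diagonal."""
    if len(matrix) < 3:
        raise ValueError(f"need >= 3 observations, got {len(matrix)}")
    sd = matrix.std(axis=0, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"zero-variance column(s): {constant}")
    return matrix.corr(method="pearson")
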