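"""Simulated feature→performance tables with known linear coefficients."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .designs import DESIGN_COLUMNS, FEATURE_NAMES, SyntheticFamilySpec, enumerate_design_space


def simulate_performance(
    features: pd.DataFrame | None,
    spec: SyntheticFamilySpec,
) -> pd.DataFrame:
    """Generate a performance table from features via a planted linear model.

    The response is ``baseline + X_std @ beta + Normal(0, noise_sd)`` on the
    linear scale, where ``X_std`` holds the feature columns standardized to
    mean 0 / sd 1 (ddof=1). With ``skew="exponential"`` the on-state signal
    is ``10**response`` — right-skewed, with log10 recovering linearity.
    Fold induction is generated the same way from ``beta_fi`` (default:
    ``beta``) with an independent noise draw. Deterministic per seed.

    If ``features`` is None (or lacks the planted feature columns), a design
    table is enumerated and standard-normal feature values are drawn for the
    missing columns.
    """
    rng = np.random.default_rng(spec.seed)
    beta = dict(spec.beta) if spec.beta else {name: 0.0 for name in FEATURE_NAMES}
    beta_fi = dict(spec.beta_fi) if spec.beta_fi is not None else dict(beta)

    if features is None:
        table = enumerate_design_space(spec)
    else:
        table = features.copy()
    if "design_id" not in table.columns:
        raise ValueError("features table must carry a design_id column")

    for name in beta:
        if name not in table.columns:
            table[name] = rng.standard_normal(len(table))

    order = list(beta)
    X = table[order].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        constant = [order[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant feature column(s): {constant}")
    X_std = (X - mu) / sd

    b = np.array([beta[name] for name in order])
    b_fi = np.array([beta_fi.get(name, 0.0) for name in order])
    y_os = spec.baseline + X_std @ b + rng.normal(0.0, spec.noise_sd, len(table))
    y_fi = spec.baseline + X_std @ b_fi + rng.normal(0.0, spec.noise_sd, len(table))
    if spec.skew == "exponential":
        os_vals = np.power(10.0, y_os)
        fi_vals = np.power(10.0, y_fi)
    else:
        os_vals = y_os
        fi_vals = y_fi

    out = table.copy()
    out["os_meptr"] = os_vals
    out["fi"] = fi_vals
    lead = [c for c in DESIGN_COLUMNS if c in out.columns] + ["os_meptr", "fi"]
    rest = [c for c in out.columns if c not in lead]
    return out[lead + rest]
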