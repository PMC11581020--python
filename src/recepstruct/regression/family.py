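"""Per-family analysis workflow: transforms, fits, reductions, reporting.

Order of operations for one receptor family:

1. optional log10 of the dependent variable;
2. single-feature regressions;
3. Pearson correlation matrix of the structural features;
4. full structural model on standardized features;
5. VIF screening (threshold 10) then backward elimination (α = 0.05) →
   reduced structural model;
6. full and reduced categorical (one-hot) models — backward elimination
   only, no VIF phase, unless configured otherwise;
7. optional combined model over the union of reduced structural and
   reduced categorical features.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .encoding import CATEGORICAL_FACTORS, one_hot_encode
from .ols import RegressionFit, ols_fit, simple_regressions
from .selection import ALPHA, VIF_THRESHOLD, ReductionTrace, backward_eliminate, reduce_by_vif
from .transforms import log_transform, pearson_correlation_matrix, standardize

STRUCTURAL_FEATURES = [
    "ecd_distance",
    "ecd_contacts",
    "tmd_distance",
    "tmd_contacts",
    "tmd_crossing_angle",
    "tmd_exit_angle",
]


@dataclass
class FamilyConfig:
    family: str = "family"
    dv: str = "os"  # {"os", "fi"}
    log_dv: bool = False
    vif_threshold: float = VIF_THRESHOLD
    alpha: float = ALPHA
    combined: bool = True
    categorical_vif: bool = False  # paper workflow: no VIF phase for categoricals
    features: list[str] = field(default_factory=lambda: list(STRUCTURAL_FEATURES))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "dv": self.dv,
            "log_dv": self.log_dv,
            "vif_threshold": self.vif_threshold,
            "alpha": self.alpha,
            "combined": self.combined,
            "categorical_vif": self.categorical_vif,
            "features": self.features,
        }


@dataclass
class AnalysisReport:
    config: dict
    n_obs: int
    single_feature: pd.DataFrame
    correlation: pd.DataFrame
    full_structural: RegressionFit
    vif_trace: ReductionTrace
    elimination_trace: ReductionTrace
    reduced_structural: RegressionFit
    full_categorical: Optional[RegressionFit] = None
    categorical_trace: Optional[ReductionTrace] = None
    reduced_categorical: Optional[RegressionFit] = None
    combined: Optional[RegressionFit] = None

    def to_dict(self) -> dict:
        out = {
            "config": self.config,
            "n_obs": self.n_obs,
            "single_feature": self.single_feature.to_dict(orient="records"),
            "correlation": {
                str(row): {str(col): float(self.correlation.loc[row, col]) for col in self.correlation.columns}
                for row in self.correlation.index
            },
            "full_structural": self.full_structural.to_dict(),
            "vif_trace": self.vif_trace.to_dict(),
            "elimination_trace": self.elimination_trace.to_dict(),
            "reduced_structural": self.reduced_structural.to_dict(),
        }
        if self.full_categorical is not None:
            out["full_categorical"] = self.full_categorical.to_dict()
        if self.categorical_trace is not None:
            out["categorical_trace"] = self.categorical_trace.to_dict()
        if self.reduced_categorical is not None:
            out["reduced_categorical"] = self.reduced_categorical.to_dict()
        if self.combined is not None:
            out["combined"] = self.combined.to_dict()
        return out

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("default", _json_default)
        return json.dumps(self.to_dict(), **kwargs)

    def to_markdown(self) -> str:
        lines = [f"# Analysis report — {self.config.get('family')}", ""]
        lines.append(f"- dependent variable: {self.config.get('dv')}"
                     f"{' (log10)' if self.config.get('log_dv') else ''}")
        lines.append(f"- observations: {self.n_obs}")
        lines.append("")
        lines.append("## Single-feature regressions")
        lines.append(self.single_feature.to_markdown(index=False, floatfmt=".3f"))
        lines.append("")

        def fit_block(title: str, fit: RegressionFit) -> None:
            lines.append(f"## {title}")
            lines.append(
                f"R² = {fit.r_squared:.3f}, adjusted R² = {fit.adj_r_squared:.3f}, "
                f"n = {fit.n_obs}, k = {fit.k_features}"
            )
            rows = [
                {
                    "feature": name,
                    "coef": fit.coefficients[name],
                    "std_err": fit.std_errors[name],
                    "p": fit.p_values[name],
                    "ci_low": fit.conf_intervals[name][0],
                    "ci_high": fit.conf_intervals[name][1],
                }
                for name in fit.feature_names
            ]
            if rows:
                lines.append(pd.DataFrame(rows).to_markdown(index=False, floatfmt=".4f"))
            else:
                lines.append("(intercept-only model)")
            lines.append("")

        fit_block("Full structural model", self.full_structural)
        fit_block("Reduced structural model", self.reduced_structural)
        if self.full_categorical is not None:
            fit_block("Full categorical model", self.full_categorical)
        if self.reduced_categorical is not None:
            fit_block("Reduced categorical model", self.reduced_categorical)
        if self.combined is not None:
            fit_block("Combined model", self.combined)

        if self.vif_trace.steps or self.elimination_trace.steps:
            lines.append("## Structural reduction trace")
            for step in self.vif_trace.steps + self.elimination_trace.steps:
                lines.append(f"- removed `{step.removed}` ({step.criterion} = {step.value:.3g})")
            lines.append("")
        return "\n".join(lines)


def _json_default(obj):
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"Object of type {type(obj).__name__} is not JSON serializable")


class JoinError(ValueError):
    pass


def _join_tables(features: pd.DataFrame, performance: pd.DataFrame) -> pd.DataFrame:
    f_ids = set(features["design_id"])
    p_ids = set(performance["design_id"])
    if f_ids != p_ids:
        only_f = sorted(f_ids - p_ids)
        only_p = sorted(p_ids - f_ids)
        raise JoinError(
            f"design_id mismatch; only in features: {only_f}; only in performance: {only_p}"
        )
    merged = features.merge(performance, on="design_id", validate="one_to_one")
    return merged.sort_values("design_id").reset_index(drop=True)


def run_family_analysis(
    features: pd.DataFrame,
    performance: pd.DataFrame,
    config: Optional[FamilyConfig] = None,
) -> AnalysisReport:
    """Run the full structural + categorical regression workflow for a family."""
    config = config or FamilyConfig()
    data = _join_tables(features, performance)

    dv_column = {"os": "os_meptr", "fi": "fi"}.get(config.dv, config.dv)
    if dv_column not in data.columns:
        raise ValueError(f"dependent variable column {dv_column!r} not in performance table")
    y = data[dv_column].astype(float)
    if config.log_dv:
        y = log_transform(y)

    feature_cols = [f for f in config.features if f in data.columns]
    if not feature_cols:
        raise ValueError(f"none of the feature columns {config.features} present")
    # drop features that are constant across the family (e.g. zero contacts
    # everywhere): they carry no variation and cannot be standardized
    usable, dropped = [], []
    for col in feature_cols:
        if data[col].astype(float).std(ddof=1) == 0:
            dropped.append(col)
        else:
            usable.append(col)
    X_raw = data[usable].astype(float)
    X_std = standardize(X_raw)

    single = simple_regressions(X_raw, y)
    corr = pearson_correlation_matrix(X_raw)

    full_structural = ols_fit(X_std, y)
    if dropped:
        full_structural.notes.append(f"constant feature(s) excluded: {dropped}")
    kept, vif_trace = reduce_by_vif(X_std, threshold=config.vif_threshold)
    reduced_structural, elim_trace = backward_eliminate(kept, y, alpha=config.alpha)

    full_categorical = None
    categorical_trace = None
    reduced_categorical = None
    combined = None
    has_categoricals = all(c in data.columns for c in CATEGORICAL_FACTORS)
    if has_categoricals:
        encoded = one_hot_encode(data[CATEGORICAL_FACTORS])
        full_categorical = ols_fit(encoded, y, force=True)
        cat_input = encoded
        if config.categorical_vif:
            cat_input, cat_vif_trace = reduce_by_vif(encoded, threshold=config.vif_threshold)
        reduced_categorical, categorical_trace = backward_eliminate(
            cat_input, y, alpha=config.alpha
        )
        if config.combined:
            struct_part = X_std[reduced_structural.feature_names]
            cat_part = encoded[reduced_categorical.feature_names]
            combined_X = pd.concat([struct_part, cat_part], axis=1)
            if combined_X.shape[1] > 0:
                combined = ols_fit(combined_X, y)

    return AnalysisReport(
        config=config.to_dict(),
        n_obs=len(data),
        single_feature=single,
        correlation=corr,
        full_structural=full_structural,
        vif_trace=vif_trace,
        elimination_trace=elim_trace,
        reduced_structural=reduced_structural,
        full_categorical=full_categorical,
        categorical_trace=categorical_trace,
        reduced_categorical=reduced_categorical,
        combined=combined,
    )
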