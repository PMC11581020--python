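"""One-hot encoding of categorical receptor design columns.

Every level of every factor gets a column — no reference level is dropped —
so each factor's level-columns sum to 1 in every row. The ligand factor is
encoded only when more than one ligand level is present. Column order is
deterministic: factor (chain role first), then level, lexicographic.
"""
from __future__ import annotations

import pandas as pd

CATEGORICAL_FACTORS = ["ntev_ecd", "ntev_tmd", "ctev_ecd", "ctev_tmd", "ligand"]


def one_hot_encode(designs: pd.DataFrame, factors: list[str] | None = None) -> pd.DataFrame:
    factors = factors or CATEGORICAL_FACTORS
    missing = [f for f in factors if f not in designs.columns]
    if missing:
        raise ValueError(f"design table missing categorical column(s): {missing}")
    if designs.empty:
        raise ValueError("design table is empty")

    columns: dict[str, pd.Series] = {}
    for factor in factors:
        levels = sorted(designs[factor].astype(str).unique())
        if factor == "ligand" and len(levels) < 2:
            continue
        for level in levels:
            columns[f"{factor}={level}"] = (
                (designs[factor].astype(str) == level).astype(int)
            )
    return pd.DataFrame(columns, index=designs.index)
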