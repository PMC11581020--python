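"""Combinatorial receptor design-space enumeration.

A design pairs an NTEVp-role chain variant with a CTEVp-role chain variant
and a ligand. A chain variant is an ECD joined with an admissible TMD: by
default each ECD admits its own natural TMD plus any shared TMD (e.g.
CD28); a full Cartesian ECD × TMD product is available as an option.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import pandas as pd

DESIGN_COLUMNS = ["design_id", "ntev_ecd", "ntev_tmd", "ctev_ecd", "ctev_tmd", "ligand"]


@dataclass
class FamilyDesignSpace:
    name: str
    ecd_levels: list[str]
    natural_tmds: dict[str, str]  # ECD -> its own TMD
    shared_tmds: list[str]
    ligand_levels: list[str]

    def chain_variants(self, full_cartesian: bool = False) -> list[tuple[str, str]]:
        variants: list[tuple[str, str]] = []
        tmd_levels = self.tmd_levels
        for ecd in self.ecd_levels:
            if full_cartesian:
                admissible = tmd_levels
            else:
                admissible = [self.natural_tmds[ecd]] + list(self.shared_tmds)
            for tmd in admissible:
                variants.append((ecd, tmd))
        return variants

    @property
    def tmd_levels(self) -> list[str]:
        seen: list[str] = []
        for tmd in list(self.natural_tmds.values()) + list(self.shared_tmds):
            if tmd not in seen:
                seen.append(tmd)
        return seen


# The four natural-ectodomain receptor families analysed in this package.
PAPER_FAMILIES: dict[str, FamilyDesignSpace] = {
    "vegf": FamilyDesignSpace(
        name="vegf",
        ecd_levels=["VEGFR1", "VEGFR2"],
        natural_tmds={"VEGFR1": "VEGFR1-TMD", "VEGFR2": "VEGFR2-TMD"},
        shared_tmds=["CD28-TMD"],
        ligand_levels=["VEGFA121", "VEGFA165"],
    ),
    "tnf": FamilyDesignSpace(
        name="tnf",
        ecd_levels=["TNFR1", "TNFR2"],
        natural_tmds={"TNFR1": "TNFR1-TMD", "TNFR2": "TNFR2-TMD"},
        shared_tmds=["CD28-TMD"],
        ligand_levels=["soluble-TNF", "proTNF", "proTNF-altSP"],
    ),
    "il10": FamilyDesignSpace(
        name="il10",
        ecd_levels=["IL-10Ra", "IL-10Rb"],
        natural_tmds={"IL-10Ra": "IL-10Ra-TMD", "IL-10Rb": "IL-10Rb-TMD"},
        shared_tmds=["CD28-TMD"],
        ligand_levels=["IL-10"],
    ),
    "tgfb": FamilyDesignSpace(
        name="tgfb",
        ecd_levels=["TGFbR1", "TGFbR2"],
        natural_tmds={"TGFbR1": "TGFbR1-TMD", "TGFbR2": "TGFbR2-TMD"},
        shared_tmds=["CD28-TMD"],
        ligand_levels=["TGFb"],
    ),
}

FEATURE_NAMES = [
    "ecd_distance",
    "ecd_contacts",
    "tmd_distance",
    "tmd_contacts",
    "tmd_crossing_angle",
    "tmd_exit_angle",
]


@dataclass
class SyntheticFamilySpec:
    """Design structure plus the planted feature→performance relationship."""

    design_space: FamilyDesignSpace = field(
        default_factory=lambda: PAPER_FAMILIES["vegf"]
    )
    beta: dict[str, float] = field(default_factory=dict)  # per standardized feature
    beta_fi: Optional[dict[str, float]] = None  # defaults to beta
    baseline: float = 2.0  # intercept on the (possibly log) response scale
    noise_sd: float = 0.5
    skew: str = "none"  # {"none", "exponential"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.skew not in ("none", "exponential"):
            raise ValueError("skew must be 'none' or 'exponential'")


def enumerate_design_space(
    family: Union[str, FamilyDesignSpace, SyntheticFamilySpec],
    full_cartesian: bool = False,
) -> pd.DataFrame:
    """Cartesian product of NTEVp variants × CTEVp variants × ligands."""
    if isinstance(family, SyntheticFamilySpec):
        space = family.design_space
    elif isinstance(family, str):
        try:
            space = PAPER_FAMILIES[family.lower()]
        except KeyError:
            raise KeyError(
                f"unknown family {family!r}; known: {sorted(PAPER_FAMILIES)}"
            ) from None
    else:
        space = family
    if not space.ecd_levels or not space.ligand_levels:
        raise ValueError("ECD and ligand level lists must be non-empty")

    variants = space.chain_variants(full_cartesian=full_cartesian)
    rows = []
    for n_ecd, n_tmd in variants:
        for c_ecd, c_tmd in variants:
            for ligand in space.ligand_levels:
                design_id = f"{n_ecd}.{n_tmd}_x_{c_ecd}.{c_tmd}_{ligand}"
                rows.append(
                    {
                        "design_id": design_id,
                        "ntev_ecd": n_ecd,
                        "ntev_tmd": n_tmd,
                        "ctev_ecd": c_ecd,
                        "ctev_tmd": c_tmd,
                        "ligand": ligand,
                    }
                )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def count_receptor_pairings(
    family: Union[str, FamilyDesignSpace], full_cartesian: bool = False
) -> int:
    table = enumerate_design_space(family, full_cartesian=full_cartesian)
    return len(
        table[["ntev_ecd", "ntev_tmd", "ctev_ecd", "ctev_tmd"]].drop_duplicates()
    )
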