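"""Per-design feature assembly: manifests, averaging rules, feature tables."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from ..structure.io import read_structure
from ..structure.model import Structure
from ..structure.secondary import SSAssignment, assign_secondary_structure
from .contacts import ContactParams, interchain_contacts
from .geometry import (
    ecd_terminal_distance,
    tmd_crossing_angle,
    tmd_exit_angle,
    tmd_terminal_distance,
)

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "ecd_distance",
    "ecd_contacts",
    "tmd_distance",
    "tmd_contacts",
    "tmd_crossing_angle",
    "tmd_exit_angle",
]

FEATURE_UNITS = {
    "ecd_distance": "Å",
    "ecd_contacts": "count",
    "tmd_distance": "Å",
    "tmd_contacts": "count",
    "tmd_crossing_angle": "degrees (signed)",
    "tmd_exit_angle": "degrees in [0, 180]",
}

MANIFEST_COLUMNS = [
    "design_id",
    "structure_file",
    "receptor_chain_a",
    "receptor_chain_b",
    "ligand_chains",
    "complex_kind",
    "tmd_file_ab",
    "tmd_file_ba",
]


@dataclass
class ECDFeatures:
    ecd_distance: float
    ecd_contacts: float


@dataclass
class TMDFeatures:
    tmd_distance: float
    tmd_contacts: float
    tmd_crossing_angle: float
    tmd_exit_angle: float


@dataclass
class FeatureVector:
    ecd_distance: float
    ecd_contacts: float
    tmd_distance: float
    tmd_contacts: float
    tmd_crossing_angle: float
    tmd_exit_angle: float

    def __post_init__(self) -> None:
        if self.ecd_distance < 0 or self.tmd_distance < 0:
            raise ValueError("distances must be >= 0")
        if self.ecd_contacts < 0 or self.tmd_contacts < 0:
            raise ValueError("contact counts must be >= 0")
        if not 0.0 <= self.tmd_exit_angle <= 180.0:
            raise ValueError("exit angle must lie in [0, 180]")


@dataclass
class ComplexManifestRow:
    design_id: str
    structure_file: str
    receptor_chain_a: str  # tetramers: '+'-separated pair of chain ids
    receptor_chain_b: str
    ligand_chains: list[str] = field(default_factory=list)
    complex_kind: str = "dimer"  # {dimer, tetramer}
    tmd_file_ab: str = ""
    tmd_file_ba: str = ""  # empty for homodimeric TMD pairings

    def __post_init__(self) -> None:
        if self.complex_kind not in ("dimer", "tetramer"):
            raise ValueError(f"complex_kind must be dimer or tetramer, got {self.complex_kind!r}")
        if self.receptor_chain_a == self.receptor_chain_b:
            raise ValueError(f"{self.design_id}: receptor chain ids must be distinct")


@dataclass
class FeatureConfig:
    contact_params: ContactParams = field(default_factory=ContactParams)
    ss_energy_cutoff: float = -0.5
    exit_angle_projected: bool = True
    skip_errors: bool = False


class FeatureExtractionError(Exception):
    def __init__(self, failures: dict[str, str]):
        self.failures = failures
        details = "; ".join(f"{k}: {v}" for k, v in failures.items())
        super().__init__(f"feature extraction failed for {len(failures)} design(s): {details}")


def measure_ecd_pair(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    ss: SSAssignment,
    params: ContactParams,
) -> ECDFeatures:
    return ECDFeatures(
        ecd_distance=ecd_terminal_distance(structure, chain_a, chain_b, ss),
        ecd_contacts=float(interchain_contacts(structure, chain_a, chain_b, params).count),
    )


def measure_tmd_dimer(dimer: Structure, config: FeatureConfig) -> TMDFeatures:
    a, b = dimer.chain_ids
    return TMDFeatures(
        tmd_distance=tmd_terminal_distance(dimer),
        tmd_contacts=float(interchain_contacts(dimer, a, b, config.contact_params).count),
        tmd_crossing_angle=tmd_crossing_angle(dimer),
        tmd_exit_angle=tmd_exit_angle(dimer, projected=config.exit_angle_projected),
    )


def average_ordered_tmd_features(features_ab: TMDFeatures, features_ba: TMDFeatures) -> TMDFeatures:
    """Arithmetic mean over the two orderings of a heterodimeric TMD pair."""
    return TMDFeatures(
        tmd_distance=(features_ab.tmd_distance + features_ba.tmd_distance) / 2.0,
        tmd_contacts=(features_ab.tmd_contacts + features_ba.tmd_contacts) / 2.0,
        tmd_crossing_angle=(features_ab.tmd_crossing_angle + features_ba.tmd_crossing_angle) / 2.0,
        tmd_exit_angle=(features_ab.tmd_exit_angle + features_ba.tmd_exit_angle) / 2.0,
    )


def tetramer_ecd_features(
    structure: Structure,
    alpha_chains: tuple[str, str],
    beta_chains: tuple[str, str],
    ss: SSAssignment,
    params: ContactParams,
) -> tuple[ECDFeatures, list[tuple[str, str]]]:
    """ECD features for a 2α+2β receptor tetramer.

    Of the two perfect α↔β matchings, the one minimizing the summed terminal
    distance is selected (the chains 'closest to one another'); the returned
    features are the arithmetic mean over the two matched pairs.
    """
    a1, a2 = alpha_chains
    b1, b2 = beta_chains
    matchings = [
        [(a1, b1), (a2, b2)],
        [(a1, b2), (a2, b1)],
    ]
    scored = []
    for matching in matchings:
        total = sum(
            ecd_terminal_distance(structure, x, y, ss) for x, y in matching
        )
        scored.append((total, matching))
    _, best = min(scored, key=lambda item: item[0])
    pair_features = [measure_ecd_pair(structure, x, y, ss, params) for x, y in best]
    averaged = ECDFeatures(
        ecd_distance=sum(f.ecd_distance for f in pair_features) / 2.0,
        ecd_contacts=sum(f.ecd_contacts for f in pair_features) / 2.0,
    )
    return averaged, best


def _split_ids(raw: str) -> list[str]:
    return [tok for tok in raw.replace(";", "+").split("+") if tok]


def read_manifest(path: str | Path) -> list[ComplexManifestRow]:
    """Read a manifest CSV; file paths are resolved relative to the manifest."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing required column(s) {missing}")
    base = path.parent
    rows = []
    for record in frame.to_dict("records"):
        for key in ("structure_file", "tmd_file_ab", "tmd_file_ba"):
            if record[key]:
                record[key] = str((base / record[key]).resolve())
        rows.append(
            ComplexManifestRow(
                design_id=record["design_id"],
                structure_file=record["structure_file"],
                receptor_chain_a=record["receptor_chain_a"],
                receptor_chain_b=record["receptor_chain_b"],
                ligand_chains=_split_ids(record["ligand_chains"]),
                complex_kind=record["complex_kind"] or "dimer",
                tmd_file_ab=record["tmd_file_ab"],
                tmd_file_ba=record["tmd_file_ba"],
            )
        )
    return rows


def extract_row_features(row: ComplexManifestRow, config: FeatureConfig) -> FeatureVector:
    structure = read_structure(row.structure_file)
    for chain_id in row.ligand_chains:
        structure.chain(chain_id).role = "ligand"
    ss = assign_secondary_structure(structure, energy_cutoff=config.ss_energy_cutoff)

    if row.complex_kind == "tetramer":
        alphas = _split_ids(row.receptor_chain_a)
        betas = _split_ids(row.receptor_chain_b)
        if len(alphas) != 2 or len(betas) != 2:
            raise ValueError(
                f"{row.design_id}: tetramer rows need two '+'-separated chain ids per side"
            )
        ecd, _ = tetramer_ecd_features(
            structure, (alphas[0], alphas[1]), (betas[0], betas[1]), ss,
            config.contact_params,
        )
    else:
        ecd = measure_ecd_pair(
            structure, row.receptor_chain_a, row.receptor_chain_b, ss,
            config.contact_params,
        )

    tmd_ab = measure_tmd_dimer(read_structure(row.tmd_file_ab), config)
    if row.tmd_file_ba:
        tmd_ba = measure_tmd_dimer(read_structure(row.tmd_file_ba), config)
        tmd = average_ordered_tmd_features(tmd_ab, tmd_ba)
    else:
        tmd = tmd_ab

    return FeatureVector(
        ecd_distance=ecd.ecd_distance,
        ecd_contacts=ecd.ecd_contacts,
        tmd_distance=tmd.tmd_distance,
        tmd_contacts=tmd.tmd_contacts,
        tmd_crossing_angle=tmd.tmd_crossing_angle,
        tmd_exit_angle=tmd.tmd_exit_angle,
    )


def build_feature_table(
    manifest: list[ComplexManifestRow],
    config: Optional[FeatureConfig] = None,
) -> pd.DataFrame:
    """One feature vector per design; deterministic; per-row failures collected."""
    config = config or FeatureConfig()
    records = []
    failures: dict[str, str] = {}
    for row in manifest:
        try:
            fv = extract_row_features(row, config)
        except Exception as exc:  # per-row isolation; re-raised unless skip_errors
            failures[row.design_id] = f"{type(exc).__name__}: {exc}"
            logger.error("design %s failed: %s", row.design_id, exc)
            continue
        records.append({"design_id": row.design_id, **fv.__dict__})
    if failures and not config.skip_errors:
        raise FeatureExtractionError(failures)
    return pd.DataFrame(records, columns=["design_id"] + FEATURE_COLUMNS)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    units = ", ".join(f"{k}: {v}" for k, v in FEATURE_UNITS.items())
    with open(path, "w") as fh:
        fh.write(f"# units — {units}\n")
        table.to_csv(fh, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
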