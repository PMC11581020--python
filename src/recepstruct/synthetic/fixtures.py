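"""Write a complete synthetic dataset to disk: structures, manifest,
performance table and planted ground truth. Used by the demo subcommand and
by end-to-end tests."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..features.table import MANIFEST_COLUMNS
from ..structure.io import write_structure
from .complexes import DimerSpec, make_ecd_complex, make_tmd_dimer
from .designs import SyntheticFamilySpec, enumerate_design_space
from .helix import HelixSpec


def generate_demo_dataset(
    out_dir: str | Path,
    seed: int = 0,
    spec: SyntheticFamilySpec | None = None,
) -> dict[str, Path]:
    """Generate per-design structures plus a manifest and design table.

    Each design in the enumerated space gets an ECD complex and a TMD dimer
    whose construction parameters are drawn deterministically from the seed,
    so extracted features vary across designs. Returns paths to the written
    artifacts; the performance table is produced separately, from the
    extracted features, so that planted coefficients are recoverable.
    """
    spec = spec or SyntheticFamilySpec(seed=seed)
    out_dir = Path(out_dir)
    structures_dir = out_dir / "structures"
    structures_dir.mkdir(parents=True, exist_ok=True)

    designs = enumerate_design_space(spec)
    rng = np.random.default_rng(seed)
    n = len(designs)
    crossing = rng.uniform(0.0, 60.0, n)
    separation = rng.uniform(6.0, 10.5, n)
    terminal = rng.uniform(18.0, 45.0, n)
    gap = rng.uniform(1.0, 6.0, n)
    phase = rng.uniform(0.0, 360.0, n)

    manifest_rows = []
    for i, design_id in enumerate(designs["design_id"]):
        ecd = make_ecd_complex(
            terminal_distance=float(terminal[i]),
            interface_gap=float(gap[i]),
            seed=int(rng.integers(0, 2**31)),
            with_ligand=True,
        )
        dimer = make_tmd_dimer(
            DimerSpec(
                helix_a=HelixSpec(n_residues=21, phase=float(phase[i]), chain_id="A"),
                helix_b=HelixSpec(n_residues=21, phase=float(phase[i]) + 40.0, chain_id="B"),
                axis_separation=float(separation[i]),
                crossing_angle=float(crossing[i]),
            )
        )
        ecd_file = structures_dir / f"ecd_{i:03d}.pdb"
        tmd_file = structures_dir / f"tmd_{i:03d}.pdb"
        write_structure(ecd, ecd_file)
        write_structure(dimer, tmd_file)
        manifest_rows.append(
            {
                "design_id": design_id,
                "structure_file": str(ecd_file.relative_to(out_dir)),
                "receptor_chain_a": "A",
                "receptor_chain_b": "B",
                "ligand_chains": "L",
                "complex_kind": "dimer",
                "tmd_file_ab": str(tmd_file.relative_to(out_dir)),
                "tmd_file_ba": "",
            }
        )

    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, index=False)
    designs_path = out_dir / "designs.csv"
    designs.to_csv(designs_path, index=False)
    truth_path = out_dir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "seed": seed,
                "beta": spec.beta,
                "noise_sd": spec.noise_sd,
                "skew": spec.skew,
                "baseline": spec.baseline,
            },
            indent=2,
        )
        + "\n"
    )
    return {"manifest": manifest_path, "designs": designs_path, "truth": truth_path}
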