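"""Ideal α-helix backbone generator.

Backbone atoms are placed on concentric helical wheels about +Z. Wheel
radii and the phase/rise offsets of N, C and O relative to Cα were
calibrated once against a helix built from ideal internal coordinates
(φ = −57°, ψ = −47°, ω = 180°), so the geometric hydrogen-bond pattern of
a real α-helix is reproduced and H-bond-based secondary structure
assignment works on generated chains.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..structure.model import Atom, Chain, Residue

# (wheel radius Å, phase offset deg, rise offset Å) relative to the Cα wheel
_BACKBONE_WHEELS: dict[str, tuple[float, float, float]] = {
    "N": (1.552, -26.77, -0.919),
    "CA": (2.276, 0.0, 0.0),
    "C": (1.666, 26.74, 1.069),
    "O": (1.921, 20.34, 2.257),
}


@dataclass
class HelixSpec:
    n_residues: int
    rise_per_residue: float = 1.5  # Å
    twist_per_residue: float = 100.0  # degrees
    radius: float = 2.3  # Å, Cα wheel
    phase: float = 0.0  # degrees
    sequence: Optional[list[str]] = None  # default poly-Ala
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if self.n_residues < 4:
            raise ValueError(f"n_residues must be >= 4, got {self.n_residues}")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")


def ideal_helix(spec: HelixSpec, serial_start: int = 1) -> Chain:
    """Build a poly-Ala (by default) backbone helix along +Z starting at z = 0."""
    radius_scale = spec.radius / _BACKBONE_WHEELS["CA"][0]
    chain = Chain(chain_id=spec.chain_id)
    serial = serial_start
    for i in range(spec.n_residues):
        name = spec.sequence[i] if spec.sequence else "ALA"
        residue = Residue(name=name, seq_number=i + 1)
        base_phase = spec.phase + i * spec.twist_per_residue
        base_z = i * spec.rise_per_residue
        for atom_name, (wheel_r, dphi, dz) in _BACKBONE_WHEELS.items():
            phi = np.radians(base_phase + dphi)
            r = wheel_r * radius_scale
            coords = np.array([r * np.cos(phi), r * np.sin(phi), base_z + dz])
            residue.atoms.append(
                Atom(serial=serial, name=atom_name, element=atom_name[0], coords=coords)
            )
            serial += 1
        chain.residues.append(residue)
    return chain
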