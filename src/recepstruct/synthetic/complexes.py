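"""Synthetic two-chain fixtures with tunable inter-chain geometry."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..structure.model import Chain, Structure, StructureError
from .helix import HelixSpec, ideal_helix


class ConstructionError(StructureError):
    pass


def _rotation_about_x(theta_deg: float) -> np.ndarray:
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _transform_chain(chain: Chain, rotation: np.ndarray | None = None,
                     translation: np.ndarray | None = None) -> None:
    for atom in chain.atoms():
        if rotation is not None:
            atom.coords = rotation @ atom.coords
        if translation is not None:
            atom.coords = atom.coords + translation


@dataclass
class DimerSpec:
    helix_a: HelixSpec = field(default_factory=lambda: HelixSpec(n_residues=21, chain_id="A"))
    helix_b: HelixSpec = field(default_factory=lambda: HelixSpec(n_residues=21, chain_id="B"))
    axis_separation: float = 10.0  # Å
    crossing_angle: float = 0.0  # degrees, signed; + = right-handed packing
    z_offset: float = 0.0  # Å, extra vertical shift of chain B
    terminal_gap_override: Optional[float] = None  # Å, force final Cα-Cα distance

    def __post_init__(self) -> None:
        if self.axis_separation <= 0:
            raise ValueError("axis_separation must be > 0")


def make_tmd_dimer(spec: DimerSpec) -> Structure:
    """Two packed helices in the membrane frame (membrane normal = +Z).

    Chain A runs along +Z through the origin; chain B is rotated by the
    crossing angle about the inter-axis normal (+X) through its midpoint and
    shifted by ``axis_separation`` along +X. A positive crossing angle
    produces right-handed packing.
    """
    chain_a = ideal_helix(spec.helix_a, serial_start=1)
    n_atoms_a = sum(1 for _ in chain_a.atoms())
    chain_b = ideal_helix(spec.helix_b, serial_start=n_atoms_a + 1)
    if chain_a.chain_id == chain_b.chain_id:
        chain_b.chain_id = "B" if chain_a.chain_id != "B" else "C"

    mid_a = (spec.helix_a.n_residues - 1) * spec.helix_a.rise_per_residue / 2.0
    mid_b = (spec.helix_b.n_residues - 1) * spec.helix_b.rise_per_residue / 2.0
    _transform_chain(chain_b, translation=np.array([0.0, 0.0, -mid_b]))
    _transform_chain(chain_b, rotation=_rotation_about_x(spec.crossing_angle))
    _transform_chain(
        chain_b,
        translation=np.array([spec.axis_separation, 0.0, mid_a + spec.z_offset]),
    )

    if spec.terminal_gap_override is not None:
        ca_a = chain_a.residues[-1].require_atom("CA").coords
        ca_b = chain_b.residues[-1].require_atom("CA").coords
        gap_vec = ca_b - ca_a
        gap = np.linalg.norm(gap_vec)
        if gap < 1e-9:
            raise ConstructionError("terminal Cα atoms coincide; cannot set terminal gap")
        _transform_chain(
            chain_b, translation=(spec.terminal_gap_override - gap) * gap_vec / gap
        )

    for chain in (chain_a, chain_b):
        chain.role = "receptor"
    return Structure(chains=[chain_a, chain_b])


def make_ecd_complex(
    terminal_distance: float,
    interface_gap: float = 4.0,
    seed: int = 0,
    n_residues: int = 30,
    with_ligand: bool = False,
) -> Structure:
    """Two parallel helical 'ectodomain' chains with exact terminal separation.

    Chain B is chain A translated by a vector of length ``terminal_distance``
    whose horizontal component enforces ``interface_gap`` as a lower bound on
    the closest inter-chain approach; because the chains are congruent, the
    last-structured-residue Cα separation equals ``terminal_distance``
    exactly. The helix phases are drawn from ``seed``.
    """
    if terminal_distance < 0:
        raise ValueError("terminal_distance must be >= 0")
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0.0, 360.0))

    chain_a = ideal_helix(HelixSpec(n_residues=n_residues, phase=phase, chain_id="A"))
    n_atoms = sum(1 for _ in chain_a.atoms())
    chain_b = ideal_helix(
        HelixSpec(n_residues=n_residues, phase=phase, chain_id="B"),
        serial_start=n_atoms + 1,
    )

    radial_extent = float(np.max(np.hypot(*chain_a.coords()[:, :2].T)))
    dx = interface_gap + 2.0 * radial_extent
    if terminal_distance < dx:
        raise ConstructionError(
            f"terminal_distance {terminal_distance:.1f} Å infeasible with "
            f"interface_gap {interface_gap:.1f} Å (needs >= {dx:.1f} Å)"
        )
    dz = float(np.sqrt(terminal_distance**2 - dx**2))
    _transform_chain(chain_b, translation=np.array([dx, 0.0, dz]))

    chain_a.role = chain_b.role = "receptor"
    chains = [chain_a, chain_b]
    if with_ligand:
        ligand = ideal_helix(
            HelixSpec(n_residues=12, phase=phase, chain_id="L"),
            serial_start=2 * n_atoms + 1,
        )
        _transform_chain(ligand, translation=np.array([dx / 2.0, 0.0, -25.0]))
        ligand.role = "ligand"
        chains.append(ligand)
    return Structure(chains=chains)
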