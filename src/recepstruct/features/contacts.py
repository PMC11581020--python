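"""Inter-chain contact detection via van der Waals overlap.

A contact is an unordered atom pair (one atom per chain) whose vdW overlap
``r_i + r_j − d_ij`` is at least a signed cutoff (default −0.40 Å, i.e.
atoms up to 0.4 Å apart beyond their radii sum still count). Pairs within
``bond_exclusion`` covalent bonds of each other are ignored — vacuous for
distinct chains, where no covalent bonds are inferred, but enforced for
generality.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ..structure.bonds import bond_distance, infer_bonds
from ..structure.model import Structure
from ..structure.radii import VdwRadiusTable

DEFAULT_OVERLAP_CUTOFF = -0.40  # Å; viewer default contact criterion
DEFAULT_BOND_EXCLUSION = 4


@dataclass
class ContactParams:
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF
    bond_exclusion: int = DEFAULT_BOND_EXCLUSION
    radius_table: VdwRadiusTable = field(default_factory=VdwRadiusTable)

    def __post_init__(self) -> None:
        if self.bond_exclusion < 0:
            raise ValueError("bond_exclusion must be >= 0")


@dataclass
class ContactResult:
    count: int
    pairs: list[tuple[int, int]]  # (serial in chain_a, serial in chain_b)


def interchain_contacts(
    structure: Structure,
    chain_a: str,
    chain_b: str,
    params: ContactParams | None = None,
) -> ContactResult:
    """Count vdW-overlap contacts between two chains (symmetric in order)."""
    params = params or ContactParams()
    ca = structure.chain(chain_a)
    cb = structure.chain(chain_b)
    atoms_a = list(ca.atoms())
    atoms_b = list(cb.atoms())
    if not atoms_a or not atoms_b:
        return ContactResult(count=0, pairs=[])

    table = params.radius_table
    coords_a = np.array([a.coords for a in atoms_a])
    coords_b = np.array([a.coords for a in atoms_b])
    radii_a = np.array([table[a.element] for a in atoms_a])
    radii_b = np.array([table[a.element] for a in atoms_b])

    # overlap >= cutoff  <=>  d <= r_i + r_j - cutoff
    max_cut = radii_a.max() + radii_b.max() - params.overlap_cutoff
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    candidate = tree_a.query_ball_tree(tree_b, max_cut)

    graph = None
    if params.bond_exclusion > 0 and chain_a == chain_b:
        graph = infer_bonds(structure, include_hydrogens=True)

    pairs: list[tuple[int, int]] = []
    for i, hits in enumerate(candidate):
        for j in hits:
            d = np.linalg.norm(coords_a[i] - coords_b[j])
            if radii_a[i] + radii_b[j] - d < params.overlap_cutoff:
                continue
            if atoms_a[i].serial == atoms_b[j].serial and chain_a == chain_b:
                continue
            if graph is not None:
                sep = bond_distance(
                    graph, atoms_a[i].serial, atoms_b[j].serial,
                    limit=params.bond_exclusion,
                )
                if sep <= params.bond_exclusion:
                    continue
            pairs.append((atoms_a[i].serial, atoms_b[j].serial))
    pairs.sort()
    return ContactResult(count=len(pairs), pairs=pairs)
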