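"""Covalent bond inference and graph distances.

Bonds are inferred within chains only: two heavy atoms are bonded iff their
separation is at most the sum of their single-bond covalent radii plus a
0.4 Å tolerance. Hydrogens are excluded unless explicitly requested.
"""
from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import Atom, Structure
from .radii import covalent_radius

BOND_TOLERANCE = 0.4  # Å added to covalent radii sum


@dataclass
class BondGraph:
    adjacency: dict[int, set[int]] = field(default_factory=dict)

    def add_atom(self, atom_id: int) -> None:
        self.adjacency.setdefault(atom_id, set())

    def add_bond(self, a: int, b: int) -> None:
        if a == b:
            raise ValueError("self-bonds are not allowed")
        self.adjacency.setdefault(a, set()).add(b)
        self.adjacency.setdefault(b, set()).add(a)

    def __contains__(self, atom_id: int) -> bool:
        return atom_id in self.adjacency

    def neighbors(self, atom_id: int) -> set[int]:
        return self.adjacency[atom_id]

    def degree(self, atom_id: int) -> int:
        return len(self.adjacency[atom_id])

    @property
    def n_bonds(self) -> int:
        return sum(len(v) for v in self.adjacency.values()) // 2


def infer_bonds(structure: Structure, include_hydrogens: bool = False) -> BondGraph:
    """Distance-based covalent bond inference, per chain."""
    graph = BondGraph()
    for chain in structure.chains:
        atoms: list[Atom] = [
            a for a in chain.atoms() if include_hydrogens or a.element != "H"
        ]
        for atom in atoms:
            graph.add_atom(atom.serial)
        if len(atoms) < 2:
            continue
        coords = np.array([a.coords for a in atoms])
        radii = np.array([covalent_radius(a.element) for a in atoms])
        max_cut = 2 * radii.max() + BOND_TOLERANCE
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(max_cut):
            cutoff = radii[i] + radii[j] + BOND_TOLERANCE
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                graph.add_bond(atoms[i].serial, atoms[j].serial)
    return graph


def bond_distance(graph: BondGraph, a: int, b: int, limit: int | None = None) -> float:
    """Shortest path length (bond count) between two atoms; inf if disconnected.

    ``limit`` truncates the search: distances beyond it are reported as inf,
    which is all contact exclusion needs.
    """
    for atom_id in (a, b):
        if atom_id not in graph:
            raise KeyError(f"atom id {atom_id} not in bond graph")
    if a == b:
        return 0
    seen = {a}
    frontier = deque([(a, 0)])
    while frontier:
        node, dist = frontier.popleft()
        if limit is not None and dist >= limit:
            continue
        for nxt in graph.neighbors(node):
            if nxt == b:
                return dist + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, dist + 1))
    return math.inf
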