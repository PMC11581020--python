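"""Geometric features: terminal distances, helix axes, crossing and exit angles."""
from __future__ import annotations

import numpy as np

from ..structure.model import Chain, Structure, StructureError
from ..structure.secondary import SSAssignment, last_structured_residue


class ShapeError(StructureError):
    pass


class DegenerateGeometryError(StructureError):
    pass


def ecd_terminal_distance(
    structure: Structure, chain_a: str, chain_b: str, ss: SSAssignment
) -> float:
    """Cα–Cα distance (Å) between the last secondary-structure residues.

    For each receptor chain the final residue in chain order labeled H or E
    anchors the measurement; an all-coil chain is an error, never a silent
    fallback to the terminal residue.
    """
    ca_coords = []
    for chain_id in (chain_a, chain_b):
        chain = structure.chain(chain_id)
        residue = last_structured_residue(chain, ss)
        ca_coords.append(residue.require_atom("CA").coords)
    return float(np.linalg.norm(ca_coords[0] - ca_coords[1]))


def tmd_terminal_distance(dimer: Structure) -> float:
    """Cα–Cα distance (Å) between the final residues of a two-chain dimer."""
    if len(dimer.chains) != 2:
        raise ShapeError(f"expected exactly 2 chains, got {len(dimer.chains)}")
    ca = [c.residues[-1].require_atom("CA").coords for c in dimer.chains]
    return float(np.linalg.norm(ca[0] - ca[1]))


def helix_axis(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Helix axis as (unit direction oriented N→C, centroid).

    The axis is the principal direction of 4-residue sliding-window-averaged
    Cα positions, which cancels the helical wobble.
    """
    ca = chain.coords("CA")
    if len(ca) < 8:
        raise ShapeError(f"chain {chain.chain_id}: need >= 8 CA atoms, got {len(ca)}")
    smoothed = np.array([ca[i : i + 4].mean(axis=0) for i in range(len(ca) - 3)])
    centroid = smoothed.mean(axis=0)
    _, _, vt = np.linalg.svd(smoothed - centroid)
    direction = vt[0]
    if np.dot(smoothed[-1] - smoothed[0], direction) < 0:
        direction = -direction
    return direction, centroid


def tmd_crossing_angle(dimer: Structure) -> float:
    """Signed crossing angle (degrees) between two packed helices.

    Magnitude is the inter-axis angle folded to [0°, 90°]; the sign encodes
    packing handedness (right-handed positive) via the torsion of the two
    axis directions about the inter-axis vector. Invariant under chain-order
    swap.
    """
    if len(dimer.chains) != 2:
        raise ShapeError(f"expected exactly 2 chains, got {len(dimer.chains)}")
    d1, c1 = helix_axis(dimer.chains[0])
    d2, c2 = helix_axis(dimer.chains[1])
    if np.dot(d1, d2) < 0:  # fold antiparallel axes for a well-defined handedness
        d2 = -d2
    cos_theta = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
    theta = np.degrees(np.arccos(cos_theta))
    sep = c2 - c1
    sep_norm = np.linalg.norm(sep)
    if sep_norm < 1e-6:
        return float(theta)  # coincident axes: handedness undefined, report unsigned
    sign = np.sign(np.dot(np.cross(d1, d2), sep / sep_norm))
    if sign == 0:
        sign = 1.0
    return float(sign * theta)


def tmd_exit_angle(dimer: Structure, projected: bool = True) -> float:
    """Angle in [0°, 180°] between the final-residue Cα→C vectors of a dimer.

    By default the vectors are projected onto the membrane plane (XY; the
    structure must be in the membrane frame with normal = Z). ``projected=
    False`` substitutes the full-3D angle for structures lacking a frame — a
    labeled variant, not the reference definition.
    """
    if len(dimer.chains) != 2:
        raise ShapeError(f"expected exactly 2 chains, got {len(dimer.chains)}")
    vectors = []
    for chain in dimer.chains:
        final = chain.residues[-1]
        vec = final.require_atom("C").coords - final.require_atom("CA").coords
        if projected:
            vec = vec[:2]
        norm = np.linalg.norm(vec)
        if norm < 1e-6:
            raise DegenerateGeometryError(
                f"chain {chain.chain_id}: final-residue Cα→C vector has near-zero "
                f"{'XY projection' if projected else 'norm'}"
            )
        vectors.append(vec / norm)
    cos_angle = float(np.clip(np.dot(vectors[0], vectors[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos_angle)))
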