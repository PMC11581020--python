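"""Independent test oracles and geometry builders.

Everything here is deliberately written from first principles (NeRF internal
coordinates, exhaustive pair loops, normal-equation solves) so that tests
check the package against computations that share no code with it.
"""
from __future__ import annotations

import numpy as np

from recepstruct.structure.model import Atom, Chain, Residue, Structure

BOND_LENGTHS = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
BOND_ANGLES = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}


def nerf_place(a, b, c, bond, angle_deg, torsion_deg):
    """Natural extension reference frame: place atom d given a-b-c."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.cos(torsion) * np.sin(angle),
            bond * np.sin(torsion) * np.sin(angle),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def backbone_from_dihedrals(n_residues: int, phi: float, psi: float, omega: float = 180.0):
    """Backbone N/CA/C/O coordinates from ideal internal coordinates."""
    N = np.zeros(3)
    CA = np.array([BOND_LENGTHS["N-CA"], 0.0, 0.0])
    ang = np.radians(BOND_ANGLES["N-CA-C"])
    C = CA + BOND_LENGTHS["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues = [{"N": N, "CA": CA, "C": C}]
    for _ in range(1, n_residues):
        prev = residues[-1]
        N_next = nerf_place(prev["N"], prev["CA"], prev["C"], BOND_LENGTHS["C-N"], BOND_ANGLES["CA-C-N"], psi)
        CA_next = nerf_place(prev["CA"], prev["C"], N_next, BOND_LENGTHS["N-CA"], BOND_ANGLES["C-N-CA"], omega)
        C_next = nerf_place(prev["C"], N_next, CA_next, BOND_LENGTHS["CA-C"], BOND_ANGLES["N-CA-C"], phi)
        residues.append({"N": N_next, "CA": CA_next, "C": C_next})
    for i, res in enumerate(residues):
        if i < n_residues - 1:
            res["O"] = nerf_place(residues[i + 1]["N"], res["CA"], res["C"], BOND_LENGTHS["C-O"], BOND_ANGLES["CA-C-O"], 180.0)
        else:
            res["O"] = nerf_place(res["N"], res["CA"], res["C"], BOND_LENGTHS["C-O"], BOND_ANGLES["CA-C-O"], -45.0)
    return residues


def residues_to_chain(residues, chain_id="A", transform=None, serial_start=1, res_name="ALA") -> Chain:
    chain = Chain(chain_id=chain_id)
    serial = serial_start
    for i, res in enumerate(residues):
        residue = Residue(name=res_name, seq_number=i + 1)
        for name in ("N", "CA", "C", "O"):
            coords = np.array(res[name], dtype=float)
            if transform is not None:
                coords = transform(coords)
            residue.atoms.append(Atom(serial=serial, name=name, element=name[0], coords=coords))
            serial += 1
        chain.residues.append(residue)
    return chain


def ideal_strand_chain(n_residues=8, chain_id="A", serial_start=1) -> Chain:
    """Ideal β-strand (φ=−139°, ψ=135°) aligned with its axis along +x."""
    residues = backbone_from_dihedrals(n_residues, phi=-139.0, psi=135.0)
    cas = np.array([r["CA"] for r in residues])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    direction = vt[0]
    if np.dot(cas[-1] - cas[0], direction) < 0:
        direction = -direction
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(direction, x)
    c = float(np.dot(direction, x))
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rotation = np.eye(3) + vx + vx @ vx / (1.0 + c)
    for res in residues:
        for key in list(res):
            res[key] = rotation @ (res[key] - centroid)
    return residues_to_chain(residues, chain_id=chain_id, serial_start=serial_start)


def antiparallel_sheet(n_residues=8) -> Structure:
    """Two-strand antiparallel β ladder with canonical inter-strand H-bonds.

    The second strand is the first flipped 180° about z and offset by a
    registration shift tuned so backbone NH/CO pairs align.
    """
    chain_a = ideal_strand_chain(n_residues, chain_id="A")
    chain_b = ideal_strand_chain(n_residues, chain_id="B", serial_start=1000)
    for atom in chain_b.atoms():
        x, y, z = atom.coords
        atom.coords = np.array([-x + 2.4, -y + 3.2, z])
    return Structure(chains=[chain_a, chain_b])


def brute_force_contacts(structure, chain_a, chain_b, radius_table, overlap_cutoff):
    """Exhaustive all-pairs vdW-overlap contact count (O(n²) oracle)."""
    atoms_a = list(structure.chain(chain_a).atoms())
    atoms_b = list(structure.chain(chain_b).atoms())
    count = 0
    for a in atoms_a:
        for b in atoms_b:
            d = float(np.linalg.norm(a.coords - b.coords))
            if radius_table[a.element] + radius_table[b.element] - d >= overlap_cutoff:
                count += 1
    return count


def random_two_chain_structure(rng, n_atoms=20, box=8.0) -> Structure:
    """Toy structure: two chains of random heavy atoms in overlapping boxes."""
    elements = np.array(["C", "N", "O", "S"])
    chains = []
    serial = 1
    for chain_id, offset in (("A", 0.0), ("B", rng.uniform(0.0, box))):
        residue = Residue(name="UNK", seq_number=1)
        for _ in range(n_atoms):
            coords = rng.uniform(0.0, box, 3) + np.array([offset, 0.0, 0.0])
            element = str(rng.choice(elements))
            residue.atoms.append(
                Atom(serial=serial, name=f"X{serial}", element=element, coords=coords)
            )
            serial += 1
        chains.append(Chain(chain_id=chain_id, residues=[residue]))
    return Structure(chains=chains)


def normal_equation_ols(X: np.ndarray, y: np.ndarray):
    """Closed-form OLS with intercept via the normal equations."""
    design = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    residuals = y - design @ beta
    ss_res = float(residuals @ residuals)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return beta, r2


def rigid_transform(rng):
    """Random rotation matrix + translation vector."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rotation = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    translation = rng.uniform(-20.0, 20.0, 3)
    return rotation, translation


def apply_rigid(structure: Structure, rotation, translation) -> None:
    for chain in structure.chains:
        for atom in chain.atoms():
            atom.coords = rotation @ atom.coords + translation
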