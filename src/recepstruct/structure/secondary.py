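"""Hydrogen-bond-pattern secondary structure assignment (Kabsch–Sander style).

Backbone amide hydrogens are placed geometrically (1.0 Å from N, along the
previous residue's C→O direction reversed), H-bond energies use the
electrostatic model E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol with a configurable acceptance threshold (default −0.5), helices
come from i→i+4 turn patterns and strands from parallel/antiparallel bridge
ladders. Labels: H (helix), E (strand), C (coil).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model import Chain, Residue, Structure, StructureError

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_COUPLING = 0.084 * 332.0
_CA_SEARCH_RADIUS = 9.0  # Å; CA pairs beyond this cannot H-bond
_NH_BOND_LENGTH = 1.0  # Å

ResidueKey = tuple[str, int, str]


def residue_key(chain: Chain, residue: Residue) -> ResidueKey:
    return (chain.chain_id, residue.seq_number, residue.insertion_code)


@dataclass
class SSAssignment:
    labels: dict[ResidueKey, str] = field(default_factory=dict)

    def label(self, chain: Chain, residue: Residue) -> str:
        return self.labels[residue_key(chain, residue)]

    def chain_labels(self, chain: Chain) -> list[str]:
        return [self.labels[residue_key(chain, r)] for r in chain.residues]


class NoStructuredResidueError(StructureError):
    pass


class _BackboneResidue:
    __slots__ = ("chain_id", "chain_pos", "index", "key", "n", "ca", "c", "o", "h", "is_pro")

    def __init__(self, chain: Chain, chain_pos: int, residue: Residue):
        self.chain_id = chain.chain_id
        self.chain_pos = chain_pos  # position within chain order
        self.index = -1  # global index, set later
        self.key = residue_key(chain, residue)
        self.n = residue.require_atom("N").coords
        self.ca = residue.require_atom("CA").coords
        self.c = residue.require_atom("C").coords
        self.o = residue.require_atom("O").coords
        self.h: np.ndarray | None = None
        self.is_pro = residue.name == "PRO"


def _has_backbone(residue: Residue) -> bool:
    return all(residue.get_atom(name) is not None for name in ("N", "CA", "C", "O"))


def _hbond_energy(donor: _BackboneResidue, acceptor: _BackboneResidue) -> float:
    if donor.h is None or donor.is_pro:
        return 0.0
    r_on = np.linalg.norm(acceptor.o - donor.n)
    r_ch = np.linalg.norm(acceptor.c - donor.h)
    r_oh = np.linalg.norm(acceptor.o - donor.h)
    r_cn = np.linalg.norm(acceptor.c - donor.n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing/degenerate geometry
        return 0.0
    return _COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(
    structure: Structure, energy_cutoff: float = HBOND_ENERGY_CUTOFF
) -> SSAssignment:
    """Assign every residue of every chain exactly one of H/E/C.

    Deterministic for fixed input; invariant under rigid-body motion (all
    terms are interatomic distances).
    """
    assignment = SSAssignment()
    residues: list[_BackboneResidue] = []
    chain_runs: list[list[_BackboneResidue]] = []

    for chain in structure.chains:
        run: list[_BackboneResidue] = []
        n_complete = 0
        for pos, residue in enumerate(chain.residues):
            assignment.labels[residue_key(chain, residue)] = "C"
            if _has_backbone(residue):
                run.append(_BackboneResidue(chain, pos, residue))
                n_complete += 1
        if chain.residues and n_complete < 3:
            warnings.warn(
                f"chain {chain.chain_id}: fewer than 3 complete-backbone residues; "
                "assigning all coil",
                stacklevel=2,
            )
            continue
        chain_runs.append(run)

    for run in chain_runs:
        for i, res in enumerate(run):
            res.index = len(residues)
            residues.append(res)
            # amide H along previous carbonyl C->O, reversed
            if i > 0 and run[i - 1].chain_pos == res.chain_pos - 1:
                prev = run[i - 1]
                direction = prev.c - prev.o
                norm = np.linalg.norm(direction)
                if norm > 1e-9:
                    res.h = res.n + _NH_BOND_LENGTH * direction / norm

    if not residues:
        return assignment

    # candidate donor/acceptor pairs by CA proximity
    ca = np.array([r.ca for r in residues])
    tree = cKDTree(ca)
    hbond: set[tuple[int, int]] = set()  # (acceptor index, donor index)
    for i, j in tree.query_pairs(_CA_SEARCH_RADIUS):
        a, b = residues[i], residues[j]
        if a.chain_id == b.chain_id and abs(a.chain_pos - b.chain_pos) < 2:
            continue
        if _hbond_energy(b, a) < energy_cutoff:
            hbond.add((i, j))
        if _hbond_energy(a, b) < energy_cutoff:
            hbond.add((j, i))

    def hb(acceptor: int, donor: int) -> bool:
        return (acceptor, donor) in hbond

    labels = ["C"] * len(residues)

    # helix: 4-turn at i iff CO(i) accepts from NH(i+4); H spans i+1..i+4
    # when consecutive turns overlap
    for run in chain_runs:
        turns = []
        for i in range(len(run) - 4):
            contiguous = run[i + 4].chain_pos - run[i].chain_pos == 4
            turns.append(contiguous and hb(run[i].index, run[i + 4].index))
        for i in range(1, len(turns)):
            if turns[i - 1] and turns[i]:
                for k in range(i + 1, i + 5):
                    labels[run[k].index] = "H"

    # strands: Kabsch–Sander parallel/antiparallel bridge patterns
    flat = [r for run in chain_runs for r in run]
    index_of = {r.index: k for k, r in enumerate(flat)}

    def nbr(idx: int, offset: int) -> int | None:
        """Global index of the chain-contiguous neighbour, or None."""
        k = index_of[idx] + offset
        if 0 <= k < len(flat):
            other = flat[k]
            me = flat[index_of[idx]]
            if other.chain_id == me.chain_id and other.chain_pos == me.chain_pos + offset:
                return other.index
        return None

    candidates = {frozenset((i, j)) for (i, j) in hbond if _bridge_eligible(residues, i, j)}
    for pair in candidates:
        i, j = sorted(pair)
        im, ip = nbr(i, -1), nbr(i, 1)
        jm, jp = nbr(j, -1), nbr(j, 1)
        parallel = (
            (im is not None and jp is not None and hb(im, j) and hb(j, ip))
            if ip is not None
            else False
        ) or (jm is not None and jp is not None and hb(jm, i) and hb(i, jp))
        antiparallel = (hb(i, j) and hb(j, i)) or (
            im is not None
            and jp is not None
            and jm is not None
            and ip is not None
            and hb(im, jp)
            and hb(jm, ip)
        )
        if parallel or antiparallel:
            for idx in (i, j):
                if labels[idx] == "C":
                    labels[idx] = "E"

    for res, label in zip(residues, labels):
        assignment.labels[res.key] = label
    return assignment


def _bridge_eligible(residues: list[_BackboneResidue], i: int, j: int) -> bool:
    a, b = residues[i], residues[j]
    return a.chain_id != b.chain_id or abs(a.chain_pos - b.chain_pos) > 2


def last_structured_residue(chain: Chain, ss: SSAssignment) -> Residue:
    """Final residue in chain order labeled H or E.

    Raises :class:`NoStructuredResidueError` for an all-coil chain; callers
    must not silently substitute the terminal residue.
    """
    for residue in reversed(chain.residues):
        key = residue_key(chain, residue)
        if key not in ss.labels:
            raise KeyError(f"chain {chain.chain_id}: residue {key} missing from assignment")
        if ss.labels[key] in ("H", "E"):
            return residue
    raise NoStructuredResidueError(
        f"chain {chain.chain_id}: no residue assigned to a secondary structure element"
    )
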