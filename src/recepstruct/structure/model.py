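"""Hierarchical atom/residue/chain/structure model with Å coordinates."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

CHAIN_ROLES = ("receptor", "ligand", "unknown")


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    bfactor: float = 0.0  # carries per-residue pLDDT in predicted models
    altloc: str = ""
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} ({self.name}): coords must be 3 finite reals")


@dataclass
class Residue:
    name: str
    seq_number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def get_atom(self, name: str) -> Optional[Atom]:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def require_atom(self, name: str) -> Atom:
        atom = self.get_atom(name)
        if atom is None:
            raise MissingAtomError(
                f"residue {self.name} {self.seq_number}{self.insertion_code}: no atom named {name!r}"
            )
        return atom

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_number, self.insertion_code)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    role: str = "unknown"

    def __post_init__(self) -> None:
        if self.role not in CHAIN_ROLES:
            raise ValueError(f"chain role must be one of {CHAIN_ROLES}, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def atoms(self) -> Iterator[Atom]:
        for residue in self.residues:
            yield from residue.atoms

    def heavy_atoms(self) -> Iterator[Atom]:
        for atom in self.atoms():
            if atom.element != "H":
                yield atom

    def coords(self, atom_name: Optional[str] = None) -> np.ndarray:
        """Stack coordinates; restricted to one atom name (e.g. "CA") if given."""
        pts = [
            a.coords
            for a in self.atoms()
            if atom_name is None or a.name == atom_name
        ]
        if not pts:
            return np.empty((0, 3))
        return np.vstack(pts)


@dataclass
class SourceMetadata:
    tool: Optional[str] = None
    model_rank: Optional[int] = None
    ptm: Optional[float] = None
    iptm: Optional[float] = None
    f_scor: Optional[float] = None


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    source: SourceMetadata = field(default_factory=SourceMetadata)

    def __post_init__(self) -> None:
        if not self.chains:
            raise EmptyStructureError("structure must contain at least one chain")
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids: {ids}")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ChainLookupError(
            f"no chain {chain_id!r}; present: {[c.chain_id for c in self.chains]}"
        )

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]


class StructureError(Exception):
    """Base class for structure-model errors."""


class EmptyStructureError(StructureError):
    pass


class ChainLookupError(StructureError, KeyError):
    pass


class MissingAtomError(StructureError):
    pass


class PDBParseError(StructureError):
    pass
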