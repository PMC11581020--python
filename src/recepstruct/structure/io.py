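"""PDB reading (via Biopython) and writing for structures.

Reading follows wwPDB format v3.3 conventions: only the first MODEL is kept,
alternate locations are resolved to the highest-occupancy conformer (ties:
first in file order), and HETATM records are retained but flagged.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .model import (
    Atom,
    Chain,
    EmptyStructureError,
    PDBParseError,
    Residue,
    SourceMetadata,
    Structure,
)

_SUPPORTED_FORMATS = ("pdb",)


def read_structure(
    path: str | Path,
    format: str = "pdb",
    source: Optional[SourceMetadata] = None,
) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    Only MODEL 1 of multi-model files is read. Chain roles default to
    ``unknown``; callers assign roles from manifest information.
    """
    if format not in _SUPPORTED_FORMATS:
        raise ValueError(f"unsupported format {format!r}; supported: {_SUPPORTED_FORMATS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio_structure = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc

    models = list(bio_structure.get_models())
    if not models:
        raise EmptyStructureError(f"{path}: no ATOM records found")
    model = models[0]

    chains: list[Chain] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, seq_number, icode = bio_res.get_id()
            residue = Residue(
                name=bio_res.get_resname().strip(),
                seq_number=seq_number,
                insertion_code=icode.strip(),
            )
            is_het = hetflag.strip() != ""
            for bio_atom in bio_res:
                # DisorderedAtom iteration yields the selected (highest
                # occupancy, ties -> first encountered) conformer only.
                if bio_atom.is_disordered():
                    bio_atom = bio_atom.selected_child
                residue.atoms.append(
                    Atom(
                        serial=bio_atom.get_serial_number(),
                        name=bio_atom.get_name(),
                        element=(bio_atom.element or "").upper(),
                        coords=bio_atom.get_coord(),
                        occupancy=bio_atom.get_occupancy() if bio_atom.get_occupancy() is not None else 1.0,
                        bfactor=bio_atom.get_bfactor() if bio_atom.get_bfactor() is not None else 0.0,
                        altloc=(bio_atom.get_altloc() or "").strip(),
                        is_hetatm=is_het,
                    )
                )
            if residue.atoms:
                residues.append(residue)
        residues.sort(key=lambda r: r.key)
        if residues:
            chains.append(Chain(chain_id=bio_chain.get_id(), residues=residues))

    if not chains or not any(a for c in chains for a in c.atoms()):
        raise EmptyStructureError(f"{path}: no ATOM records found")
    return Structure(chains=chains, source=source or SourceMetadata())


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as wwPDB v3.3 ATOM/HETATM/TER records."""
    path = Path(path)
    lines: list[str] = []
    serial = 0
    for chain in structure.chains:
        for residue in chain.residues:
            for atom in residue.atoms:
                serial += 1
                record = "HETATM" if atom.is_hetatm else "ATOM  "
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:>5d} {name:<4.4s}{atom.altloc or ' ':1s}"
                    f"{residue.name:>3s} {chain.chain_id:1s}{residue.seq_number:>4d}"
                    f"{residue.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        last = chain.residues[-1]
        lines.append(
            f"TER   {serial:>5d}      {last.name:>3s} {chain.chain_id:1s}"
            f"{last.seq_number:>4d}{last.insertion_code or ' ':1s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
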