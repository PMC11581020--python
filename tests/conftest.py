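import numpy as np
import pytest

from recepstruct.structure.model import Atom, Chain, Residue, Structure
from recepstruct.synthetic import DimerSpec, HelixSpec, ideal_helix, make_tmd_dimer


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def helix_chain():
    return ideal_helix(HelixSpec(n_residues=20))


@pytest.fixture
def helix_structure(helix_chain):
    return Structure(chains=[helix_chain])


@pytest.fixture
def parallel_dimer():
    return make_tmd_dimer(DimerSpec(axis_separation=10.0, crossing_angle=0.0))


@pytest.fixture
def glycine_backbone():
    """Single glycine at standard internal geometry (N, CA, C, O)."""
    residue = Residue(name="GLY", seq_number=1)
    coords = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.458, 0.0, 0.0]),
        "C": np.array([1.458 + 1.525 * np.cos(np.radians(180 - 111.2)),
                       1.525 * np.sin(np.radians(180 - 111.2)), 0.0]),
    }
    # O at 1.231 Å from C, 120.8° from CA, in-plane
    ca_to_c = coords["C"] - coords["CA"]
    ca_to_c /= np.linalg.norm(ca_to_c)
    perp = np.array([-ca_to_c[1], ca_to_c[0], 0.0])
    angle = np.radians(180.0 - 120.8)
    coords["O"] = coords["C"] + 1.231 * (np.cos(angle) * ca_to_c + np.sin(angle) * perp)
    for i, (name, xyz) in enumerate(coords.items(), start=1):
        residue.atoms.append(Atom(serial=i, name=name, element=name[0], coords=xyz))
    chain = Chain(chain_id="A", residues=[residue])
    return Structure(chains=[chain])


def two_atom_structure(distance: float, element: str = "C") -> Structure:
    """Two same-element atoms in separate chains, a given distance apart."""
    chains = []
    for i, (chain_id, x) in enumerate((("A", 0.0), ("B", distance)), start=1):
        residue = Residue(name="UNK", seq_number=1)
        residue.atoms.append(
            Atom(serial=i, name=element, element=element, coords=np.array([x, 0.0, 0.0]))
        )
        chains.append(Chain(chain_id=chain_id, residues=[residue]))
    return Structure(chains=chains)
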