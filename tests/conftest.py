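import numpy as np
import pytest

from pbsfret.structure_io import Atom, Chain, Residue
from pbsfret.synthetic_data import make_helical_rod, make_ring

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def chain_from_sequence(seq: str, chain_id: str = "A", coords=None, start: int = 1) -> Chain:
    """Cα-only chain spelling out ``seq``; default coords on a gentle helix."""
    if coords is None:
        coords = [
            np.array([2.3 * np.cos(1.7 * k), 2.3 * np.sin(1.7 * k), 1.5 * k])
            for k in range(len(seq))
        ]
    residues = [
        Residue(name=THREE_LETTER[letter], seqnum=start + k, atoms=[Atom("CA", "C", coords[k])])
        for k, letter in enumerate(seq)
    ]
    return Chain(chain_id=chain_id, residues=residues)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    letters = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(letters[i] for i in rng.integers(0, len(letters), size=length))


@pytest.fixture
def ring3():
    return make_ring(3, 20.0, "tangent", seed=7)


@pytest.fixture
def rod4():
    return make_helical_rod(n_units=4, n_residues=30, seed=11)
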