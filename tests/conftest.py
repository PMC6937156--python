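import numpy as np
import pytest

from tsakit.simulate import make_toy_complex
from tsakit.structure_io import read_structure

MINI_PDB = """\
CRYST1  157.800  157.800  104.800  90.00  90.00 120.00 P 63 2 2      12
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA AALA A   1      11.639   6.071  -5.147  0.60 10.50           C
ATOM      3  CA BALA A   1      11.700   6.000  -5.100  0.40 11.00           C
ATOM      4  CA  GLY A   2       8.000   5.000  -3.000  1.00  9.00           C
ATOM      5  CA  TYR A 255       1.000   2.000   3.000  1.00  9.00           C
ATOM      6  OH  TYR A 255       1.500   2.500   3.500  1.00 12.00           O
ATOM      7  H   GLY A   2       8.100   5.100  -3.100  1.00  9.00           H
HETATM    8 ZN    ZN A 401       0.000   0.000   0.000  1.00  8.00          ZN
HETATM    9  S18 SUL A 402       3.080   0.000   0.000  1.00  8.00           S
HETATM   10  N17 SUL A 402       3.500   1.200   0.500  1.00  8.00           N
HETATM   11  N19 SUL A 402       3.600  -1.100   0.800  1.00  8.00           N
HETATM   12  O   HOH A 501       5.000   5.000   5.000  1.00 20.00           O
END
"""


@pytest.fixture
def mini_pdb_path(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINI_PDB)
    return path


@pytest.fixture
def mini_structure(mini_pdb_path):
    return read_structure(mini_pdb_path)


def grid_protein_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(0.0, 10.0, size=(n, 3))


@pytest.fixture
def toy_zn_complex():
    """Zn at origin, minimal ligand, one Tyr255 OH."""
    return make_toy_complex([
        ("CA", ("A", 255, "TYR", False), (5.0, 5.0, 0.0)),
        ("OH", ("A", 255, "TYR", False), (4.0, 1.0, 0.0)),
        ("ZN", ("A", 401, "ZN", True), (0.0, 0.0, 0.0)),
        ("S18", ("A", 402, "SUL", True), (3.08, 0.0, 0.0)),
        ("N17", ("A", 402, "SUL", True), (3.5, 1.2, 0.5)),
        ("N19", ("A", 402, "SUL", True), (3.6, -1.1, 0.8)),
    ])
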