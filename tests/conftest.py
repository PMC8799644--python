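import numpy as np
import pytest

from mdresidence.synthetic import build_peptide


GLYCINE_PDB = """\
TITLE     single glycine
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
END
"""

WATERS_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
HETATM    5  O   HOH W 101      10.000   0.000   0.000  1.00  0.00           O
HETATM    6  O   HOH W 102      13.000   0.000   0.000  1.00  0.00           O
HETATM    7  O   HOH W 103      16.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def glycine_pdb(tmp_path):
    p = tmp_path / "gly.pdb"
    p.write_text(GLYCINE_PDB)
    return p


@pytest.fixture
def waters_pdb(tmp_path):
    p = tmp_path / "waters.pdb"
    p.write_text(WATERS_PDB)
    return p


@pytest.fixture
def helix_structure():
    return build_peptide([(-57.0, -47.0)] * 8)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
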