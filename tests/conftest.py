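import pytest

import b1state as b1


@pytest.fixture(scope="session")
def tables():
    return b1.load_tables()

@pytest.fixture(scope="session")
def attested_pairs():
    return b1.load_attested_pairs()


@pytest.fixture(scope="session")
def motifs():
    return b1.load_motifs()


@pytest.fixture(scope="session")
def criteria():
    return b1.ContactCriteria()


@pytest.fixture(scope="session")
def emulation():
    """The planted paper-emulation set (noise-free, seed 1)."""
    models, truth = b1.paper_emulation_set(seed=1)
    return models, truth


MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1      11.000  22.000  33.000  1.00 20.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A  10      10.000  10.000  10.000  1.00 15.00           N
ATOM      2  CA ASER A  10      11.000  10.000  10.000  0.40 15.00           C
ATOM      3  CA BSER A  10      11.500  10.000  10.000  0.60 15.00           C
ATOM      4  OG ASER A  10      12.000  11.000  10.000  0.50 15.00           O
ATOM      5  OG BSER A  10      12.500  11.000  10.000  0.50 15.00           O
ATOM      6  O   HOH A 101      20.000  20.000  20.000  1.00 30.00           O
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
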