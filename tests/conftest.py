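import pathlib

import pytest

from protriform.fixtures import PeptideSpec, synthetic_peptide, write_pdb
from protriform.structure_io import derive_geometry

FIXTURE_DIR = pathlib.Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def peptide5():
    return synthetic_peptide(PeptideSpec(n=5, seed=7))


@pytest.fixture(scope="session")
def peptide8():
    return synthetic_peptide(PeptideSpec(n=8, seed=11))


@pytest.fixture(scope="session")
def geom5(peptide5):
    return derive_geometry(peptide5, "CA")


@pytest.fixture(scope="session")
def geom8(peptide8):
    return derive_geometry(peptide8, "CA")


@pytest.fixture(scope="session")
def pdb_text5(peptide5):
    return write_pdb(peptide5)


@pytest.fixture
def fixture_dir():
    return FIXTURE_DIR
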