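import numpy as np
import pytest

from bindfold import (
    BiasSpec,
    CGSystem,
    ModelParameters,
    ToyComplexSpec,
    build_toy_system,
    make_toy_complex,
    toy_native_map,
)

@pytest.fixture(scope="session")
def toy_spec():
    return ToyComplexSpec()


@pytest.fixture(scope="session")
def toy_bundle(toy_spec):
    """(structure, native_map, topology, unbiased CGSystem) of the default toy."""
    return build_toy_system(toy_spec)


@pytest.fixture(scope="session")
def toy_structure(toy_bundle):
    return toy_bundle[0]


@pytest.fixture(scope="session")
def toy_native_map_fixture(toy_bundle):
    return toy_bundle[1]


@pytest.fixture(scope="session")
def toy_topology(toy_bundle):
    return toy_bundle[2]


@pytest.fixture(scope="session")
def toy_system(toy_bundle):
    return toy_bundle[3]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


TWO_ATOM_PDB = """\
ATOM      1  CA  ALA A   1       1.000   1.000   1.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       4.000   1.000   1.000  1.00  0.00           C
END
"""

HETATM_ONLY_PDB = """\
HETATM    1  O   HOH A   1       1.000   1.000   1.000  1.00  0.00           O
HETATM    2  O   HOH A   2       4.000   1.000   1.000  1.00  0.00           O
END
"""


@pytest.fixture
def two_atom_pdb(tmp_path):
    p = tmp_path / "two_atoms.pdb"
    p.write_text(TWO_ATOM_PDB)
    return p


@pytest.fixture
def hetatm_only_pdb(tmp_path):
    p = tmp_path / "waters.pdb"
    p.write_text(HETATM_ONLY_PDB)
    return p
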