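"""Shared fixtures: toy proteins, landscapes, and a hand-written PDB."""

import numpy as np
import pytest

from transpath import fixtures as fx

HAND_PDB = """\
ATOM      1  N   ALA A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

# the same three residues with ATOM records deliberately out of order and
# an altloc pair on residue 2 (occupancies 0.4 / 0.6)
SHUFFLED_PDB = """\
ATOM      1  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      2  CA AGLY A   2       3.800   0.000   0.000  0.40  0.00           C
ATOM      3  CA BGLY A   2       3.900   0.000   0.000  0.60  0.00           C
ATOM      4  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def toy40():
    """40-residue hinge, 150 degree bend: the end-to-end workhorse."""
    return fx.make_toy_two_state(40, 150.0, seed=3)


@pytest.fixture(scope="session")
def toy64():
    """64-residue hinge (arms of 32): large enough for Category I rules."""
    return fx.make_toy_two_state(64, 150.0, seed=7)


@pytest.fixture(scope="session")
def double_well():
    return fx.make_analytic_landscape("double_well", shape=(41, 41),
                                      barrier=8.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
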