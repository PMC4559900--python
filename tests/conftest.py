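"""Shared fixtures: toy dimers, restraint sets and small alignments."""

from __future__ import annotations

import numpy as np
import pytest

from coevdock.alignment import encode_sequences
from coevdock.filtering import DimerRestraintSet
from coevdock.sbm import build_topology
from coevdock.synth import build_toy_dimer


@pytest.fixture(scope="session")
def toy_dimer():
    """2 x 20-bead toy homodimer with a 6-pair interface."""
    return build_toy_dimer(n=20, interface_size=6, seed=1)


@pytest.fixture(scope="session")
def toy_dimer30():
    """2 x 30-bead toy homodimer with an 8-pair interface."""
    return build_toy_dimer(n=30, interface_size=8, seed=0)


def restraints_from_pairs(pairs, di=1.0):
    """Symmetrized restraint set from unordered single-chain pairs."""
    triples = [(i, j, di) for i, j in pairs]
    inter = [(i, j, di) for i, j in pairs] + [(j, i, di) for i, j in pairs]
    return DimerRestraintSet(pairs=triples, interchain_restraints=inter)


@pytest.fixture
def toy_topology(toy_dimer):
    """SBM topology of the 20-bead toy with its native interface planted."""
    rest = restraints_from_pairs(toy_dimer.interface_pairs)
    return build_topology(toy_dimer.monomer("A"),
                          toy_dimer.native.select_chains(["B"]), rest)


@pytest.fixture
def tiny_msa():
    """4-sequence, 3-column alignment used by counting oracles."""
    return encode_sequences(["ACD", "ACD", "AC-", "GCD"],
                            ["s1", "s2", "s3", "s4"])


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       4.200   1.500   0.300  1.00  0.00           C
ATOM      5  CA  SER A   3       7.900   1.500   0.300  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C
ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
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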