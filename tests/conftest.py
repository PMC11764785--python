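"""Shared fixtures: parsed synthetic complexes and helper geometry."""

import numpy as np
import pytest

from pdbind import fixtures, structio
from pdbind.structio import Atom, Chain, ComplexStructure, Residue


@pytest.fixture(scope="session")
def toy_complex():
    """Poly-Ala helix 3.5 A from an 8-bp duplex."""
    return structio.parse_complex(
        fixtures.make_toy_complex(fixtures.FixtureSpec()))


@pytest.fixture(scope="session")
def far_complex():
    """Helix 50 A away from the duplex: no interface."""
    return structio.parse_complex(
        fixtures.make_toy_complex(fixtures.FixtureSpec(offset=50.0)))


@pytest.fixture(scope="session")
def ss_complex():
    """Helix next to a single-stranded DNA chain."""
    return structio.parse_complex(
        fixtures.make_toy_complex(fixtures.FixtureSpec(duplex=False)))


@pytest.fixture(scope="session")
def bdna_duplex():
    return structio.parse_complex(fixtures.make_bdna("ACGTACGT"))


def residue_from_coords(name, number, atoms):
    res = Residue(name, number)
    for atom_name, xyz in atoms.items():
        element = "S" if atom_name.startswith("S") else atom_name[0]
        res.atoms[atom_name] = Atom(atom_name, element, np.asarray(xyz, float))
    return res


def single_chain_complex(chain_id, kind, residues):
    return ComplexStructure([Chain(chain_id, kind, residues)])
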