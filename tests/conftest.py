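"""Shared fixtures: toy structures and forcefields built once per session."""

import numpy as np
import pytest

from riboswivel.forcefield import (
    BondedTerms, ContactSet, ForceField, ForceFieldParameters, build_forcefield,
)
from riboswivel.structure import AtomRecord, MolecularStructure
from riboswivel.synthetic import (
    DumbbellSpec, dumbbell_scaling_scheme, make_hinge_dumbbell, make_mini_duplex,
)


@pytest.fixture(scope="session")
def dumbbell():
    """Start/endpoint dumbbell pair with ground truth (default 22.6 deg swivel)."""
    return make_hinge_dumbbell(DumbbellSpec(seed=0))


@pytest.fixture(scope="session")
def dumbbell_ff(dumbbell):
    start, _, _ = dumbbell
    return build_forcefield(start, dumbbell_scaling_scheme())


@pytest.fixture(scope="session")
def duplex():
    return make_mini_duplex(12)


@pytest.fixture()
def harmonic_dimer():
    """Two unit-mass atoms joined by one harmonic bond of rest length 5 A."""
    params = ForceFieldParameters()
    bonded = BondedTerms(bonds=np.array([[0, 1]]), bonds_r0=np.array([5.0]))
    ff = ForceField(parameters=params, bonded=bonded, contacts=ContactSet(), n_atoms=2,
                    heavy=np.arange(2))
    ff.rebuild_noncontacts()
    coords = np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])
    return ff, coords


def backbone_dinucleotide():
    """Two-residue RNA backbone fragment (P..O3' path) on a bent path.

    The bond graph is a single 12-atom path, so the term counts are easy
    to enumerate by hand: 11 bonds, 10 angles, 9 dihedrals, no torsion
    centers.
    """
    names = ["P", "O5'", "C5'", "C4'", "C3'", "O3'"]
    atoms = []
    serial = 1
    # helical path: every bend angle ~114 deg, every torsion well defined
    for k in range(12):
        pos = np.array([1.2 * np.cos(0.7 * k), 1.2 * np.sin(0.7 * k), 0.9 * k])
        res = 1 if k < 6 else 2
        atoms.append(AtomRecord(serial, names[k % 6], names[k % 6][0], "A", res, "A", pos))
        serial += 1
    return MolecularStructure(atoms)


@pytest.fixture()
def dinucleotide():
    return backbone_dinucleotide()
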