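"""Forcefield construction: contacts, scaling, basin merging, serialization."""

import numpy as np
import pytest

from riboswivel.forcefield import (
    ForceFieldParameters, ScalingScheme, apply_scaling, build_forcefield,
    dihedral_FD, find_contacts, merge_basins,
)
from riboswivel.structure import AtomRecord, MolecularStructure
from riboswivel.energies import potential_energy


def _pair_structure(distance):
    return MolecularStructure([
        AtomRecord(1, "X1", "C", "DUM", 1, "A", np.zeros(3)),
        AtomRecord(2, "X1", "C", "DUM", 5, "A", np.array([distance, 0.0, 0.0])),
    ])


def brute_force_contacts(structure, cutoff):
    """O(N^2) oracle applying the same exclusions as find_contacts."""
    out = set()
    heavy = structure.heavy_indices()
    for a in range(len(heavy)):
        for b in range(a + 1, len(heavy)):
            i, j = int(heavy[a]), int(heavy[b])
            ai, aj = structure.atoms[i], structure.atoms[j]
            if ai.chain_id == aj.chain_id and abs(ai.res_seq - aj.res_seq) <= 1:
                continue
            if np.linalg.norm(structure.coords[i] - structure.coords[j]) <= cutoff:
                out.add((i, j))
    return out


def random_structure(rng, n_res=67):
    atoms = []
    serial = 1
    for r in range(n_res):
        chain = "A" if r < n_res // 2 else "B"
        res = r + 1 if chain == "A" else r + 1 - n_res // 2
        base = rng.uniform(0, 18, 3)
        for a in range(3):
            atoms.append(AtomRecord(serial, f"X{a+1}", "C", "DUM", res, chain,
                                    base + rng.uniform(-1, 1, 3)))
            serial += 1
    return MolecularStructure(atoms)


def test_contact_cutoff_boundary():
    assert len(find_contacts(_pair_structure(3.9))) == 1
    assert float(find_contacts(_pair_structure(3.9)).sigma[0]) == pytest.approx(3.9)
    assert len(find_contacts(_pair_structure(4.1))) == 0


def test_contacts_match_brute_force_oracle():
    rng = np.random.default_rng(11)
    for _ in range(20):
        s = random_structure(rng)
        got = {(int(i), int(j)) for i, j in find_contacts(s, 4.0).pairs}
        assert got == brute_force_contacts(s, 4.0)


def test_invalid_cutoff_rejected():
    with pytest.raises(ValueError):
        find_contacts(_pair_structure(3.0), cutoff=-1.0)


def _two_group_structure(groups):
    """One atom per chain at fixed positions; groups maps chain -> group."""
    atoms = [
        AtomRecord(1, "X1", "C", "DUM", 1, "A", np.zeros(3)),
        AtomRecord(2, "X1", "C", "DUM", 1, "B", np.array([3.5, 0.0, 0.0])),
    ]
    s = MolecularStructure(atoms)
    gdict: dict[str, list] = {}
    for c, g in groups.items():
        gdict.setdefault(g, []).append((c, None, None))
    return s, ScalingScheme(groups=gdict)


@pytest.mark.parametrize(
    "groups, expected",
    [
        ({"A": "tRNA", "B": "SSU_body"}, 0.6),
        ({"A": "SSU_head", "B": "SSU_body"}, 0.3),
        ({"A": "EFG", "B": "LSU"}, 0.6),
        ({"A": "tRNA", "B": "mRNA"}, 1.0),
        ({"A": "SSU_body", "B": "SSU_body"}, 1.0),
    ],
)
def test_group_pair_scaling_factors(groups, expected):
    s, scheme = _two_group_structure(groups)
    scaled = apply_scaling(find_contacts(s), scheme, s)
    assert float(scaled.eps[0]) == pytest.approx(expected)


def test_intersubunit_core_versus_far_scaling():
    s, scheme = _two_group_structure({"A": "SSU_body", "B": "LSU"})
    near = apply_scaling(find_contacts(s), scheme, s)
    assert float(near.eps[0]) == pytest.approx(0.3)  # midpoint 1.75 A from the core
    far_scheme = ScalingScheme(groups=scheme.groups,
                               core_point=np.array([30.0, 0.0, 0.0]))
    far = apply_scaling(find_contacts(s), far_scheme, s)
    assert float(far.eps[0]) == pytest.approx(0.1)  # midpoint ~28 A out


def test_double_scaling_rejected():
    s, scheme = _two_group_structure({"A": "tRNA", "B": "SSU_body"})
    scaled = apply_scaling(find_contacts(s), scheme, s)
    with pytest.raises(ValueError, match="already scaled"):
        apply_scaling(scaled, scheme, s)


def test_unassigned_atom_reported():
    s, _ = _two_group_structure({"A": "tRNA", "B": "SSU_body"})
    scheme = ScalingScheme(groups={"tRNA": [("A", None, None)]})
    with pytest.raises(ValueError, match="no group"):
        apply_scaling(find_contacts(s), scheme, s)


def test_dinucleotide_term_counts_match_hand_enumeration(dinucleotide):
    ff = build_forcefield(dinucleotide)
    # 12-atom path graph: 11 bonds, 10 angles, 9 dihedrals, no 3-coordinated centers
    assert len(ff.bonded.bonds) == 11
    assert len(ff.bonded.angles) == 10
    assert len(ff.bonded.dihedrals) == 9
    assert len(ff.bonded.impropers) == 0
    assert len(ff.bonded.planars) == 0
    assert bool(ff.bonded.dihedrals_backbone.all())


def test_reference_structure_is_the_energy_minimum(dumbbell, dumbbell_ff):
    start, _, _ = dumbbell
    total, parts = potential_energy(dumbbell_ff, start.coords)
    for term in ("bond", "angle", "improper", "planar",
                 "dihedral_backbone", "dihedral_sidechain"):
        assert abs(parts[term]) < 1e-18
    expected = -float(dumbbell_ff.contacts.eps.sum())
    assert parts["contact"] == pytest.approx(expected, rel=1e-9)


def test_merge_basins_identity_and_unique_count(dumbbell, dumbbell_ff):
    start, endpoint, _ = dumbbell
    same = merge_basins(dumbbell_ff, start, weight=1.0)
    assert len(same.contacts) == len(dumbbell_ff.contacts)
    merged = merge_basins(dumbbell_ff, endpoint, weight=1.0)
    end_contacts = {(int(i), int(j)) for i, j in find_contacts(
        endpoint, 4.0, bonded_pairs=dumbbell_ff.bonded.pair_set()).pairs}
    base_contacts = {(int(i), int(j)) for i, j in dumbbell_ff.contacts.pairs}
    assert len(merged.contacts) == len(base_contacts) + len(end_contacts - base_contacts)
    # merged set equals the union computed by the brute-force oracle
    merged_pairs = {(int(i), int(j)) for i, j in merged.contacts.pairs}
    assert merged_pairs == base_contacts | end_contacts
    # shared contacts keep the starting-basin width: start stays a minimum
    _, parts = potential_energy(merged, start.coords)
    assert parts["bond"] == pytest.approx(0.0, abs=1e-18)


def test_merge_basins_atom_count_mismatch(dumbbell, dumbbell_ff, duplex):
    with pytest.raises(ValueError, match="atoms"):
        merge_basins(dumbbell_ff, duplex)


def test_dihedral_fd_closed_form():
    assert dihedral_FD(0.0) == pytest.approx(0.0)
    assert dihedral_FD(np.pi) == pytest.approx(3.0)
    rng = np.random.default_rng(0)
    d = rng.uniform(-np.pi, np.pi, 16)
    np.testing.assert_allclose(dihedral_FD(d), dihedral_FD(d + 2 * np.pi), atol=1e-12)


def test_forcefield_serialization_round_trip(tmp_path, dumbbell, dumbbell_ff):
    start, endpoint, _ = dumbbell
    ff = merge_basins(dumbbell_ff, endpoint, weight=1.5)
    path = tmp_path / "ff.top"
    ff.to_file(path)
    header = path.read_text().splitlines()[1]
    assert "eps_BB" in header and "eps_SC" in header
    from riboswivel.forcefield import ForceField

    ff2 = ForceField.from_file(path)
    x = start.coords
    e1, _ = potential_energy(ff, x)
    e2, _ = potential_energy(ff2, x)
    assert e2 == pytest.approx(e1, rel=1e-12)
    assert len(ff2.noncontact_pairs) == len(ff.noncontact_pairs)


def test_parameter_validation():
    with pytest.raises(ValueError):
        ForceFieldParameters(eps_r=-1.0)
    with pytest.raises(ValueError):
        ScalingScheme(substrate_scale=0.0)
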