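"""Structure container, PDB round trips, selections and base swapping."""

import numpy as np
import pytest

from riboswivel.structure import (
    AtomRecord, MolecularStructure, PDBFormatError,
    read_pdb, write_pdb, select, center_of_mass, mutate_nucleotide,
)
from riboswivel.templates import BASE_TEMPLATES


def toy_structure():
    rows = [
        ("P", "P", "A", 1, "A", (0.0, 0.0, 0.0)),
        ("O3'", "O", "A", 1, "A", (1.5, 0.0, 0.0)),
        ("C1'", "C", "A", 1, "A", (0.7, 1.2, 0.0)),
        ("P", "P", "G", 2, "A", (3.0, 0.5, 0.2)),
        ("H5'", "H", "G", 2, "A", (3.5, 1.5, 0.2)),
        ("P", "P", "U", 1, "B", (9.0, 0.0, 1.0)),
    ]
    return MolecularStructure([
        AtomRecord(i + 1, nm, el, rn, rs, ch, np.array(xyz))
        for i, (nm, el, rn, rs, ch, xyz) in enumerate(rows)
    ])


def test_pdb_round_trip_preserves_names_numbering_coords(tmp_path):
    s = toy_structure()
    p = tmp_path / "toy.pdb"
    write_pdb(s, p)
    s2 = read_pdb(p)
    assert len(s2) == len(s)
    assert [a.name for a in s2.atoms] == [a.name for a in s.atoms]
    assert [a.res_seq for a in s2.atoms] == [a.res_seq for a in s.atoms]
    assert [a.chain_id for a in s2.atoms] == [a.chain_id for a in s.atoms]
    # PDB stores 3 decimals
    assert np.abs(s2.coords - s.coords).max() < 1.5e-3
    # idempotent: a second round trip is exact
    p2 = tmp_path / "toy2.pdb"
    write_pdb(s2, p2)
    s3 = read_pdb(p2)
    assert np.array_equal(s3.coords, s2.coords)


def test_chain_and_residue_indexes(tmp_path):
    s = toy_structure()
    p = tmp_path / "toy.pdb"
    write_pdb(s, p)
    s2 = read_pdb(p)
    assert set(s2.chain_index) == {"A", "B"}
    assert len(s2.residue_index) == 3


def test_unparseable_coordinate_field_names_line(tmp_path):
    p = tmp_path / "bad.pdb"
    good = "ATOM      1  P     A A   1       0.000   0.000   0.000  1.00  0.00           P\n"
    bad = "ATOM      2  O3'   A A   1         abc   0.000   0.000  1.00  0.00           O\n"
    p.write_text(good + bad + "END\n")
    with pytest.raises(PDBFormatError, match="line 2"):
        read_pdb(p)


def test_empty_pdb_rejected(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(PDBFormatError):
        read_pdb(p)


def test_select_conjunction_and_heavy_only():
    s = toy_structure()
    assert len(select(s, chain="A", res_seq=1, atom_names=["P"])) == 1
    # residue 2 of chain A has one heavy atom and one hydrogen
    assert len(select(s, chain="A", res_seq=2)) == 2
    assert len(select(s, chain="A", res_seq=2, heavy_only=True)) == 1


def test_empty_selection_names_predicate():
    s = toy_structure()
    with pytest.raises(ValueError, match="res_seq"):
        select(s, chain="A", res_seq=9999)


def test_center_of_mass_cases():
    s = MolecularStructure([
        AtomRecord(1, "X1", "C", "DUM", 1, "A", np.zeros(3)),
        AtomRecord(2, "X2", "C", "DUM", 1, "A", np.array([2.0, 0.0, 0.0])),
    ])
    np.testing.assert_allclose(center_of_mass(select(s)), [1.0, 0.0, 0.0])
    np.testing.assert_allclose(center_of_mass(select(s, atom_names=["X1"])),
                               [0.0, 0.0, 0.0])
    # equilateral triangle centered on the origin
    ang = np.radians([90.0, 210.0, 330.0])
    r = 2.0 / np.sqrt(3.0)
    tri = MolecularStructure([
        AtomRecord(i + 1, f"X{i+1}", "C", "DUM", 1, "A",
                   np.array([r * np.cos(a), r * np.sin(a), 0.0]))
        for i, a in enumerate(ang)
    ])
    np.testing.assert_allclose(center_of_mass(select(tri)), np.zeros(3), atol=1e-12)


def test_whole_com_equals_weighted_chain_coms(dumbbell):
    start, _, _ = dumbbell
    total = center_of_mass(select(start))
    acc = np.zeros(3)
    n = 0
    for ch in start.chains():
        sel = select(start, chain=ch)
        acc += center_of_mass(sel) * len(sel)
        n += len(sel)
    np.testing.assert_allclose(total, acc / n, atol=1e-10)


def _toy_nucleotide(base):
    tmpl = BASE_TEMPLATES[base]
    atoms = [AtomRecord(i + 1, nm, nm[0], base, 1, "A", xyz + np.array([3.0, -1.0, 2.0]))
             for i, (nm, xyz) in enumerate(tmpl.items())]
    atoms.append(AtomRecord(len(atoms) + 1, "O3'", "O", base, 1, "A",
                            np.array([8.0, -1.0, 2.0])))
    return MolecularStructure(atoms)


def test_mutation_identity_and_backbone_preservation():
    s = _toy_nucleotide("A")
    same = mutate_nucleotide(s, "A", 1, "A")
    for nm in BASE_TEMPLATES["A"]:
        np.testing.assert_allclose(
            same.coords[same.atom_index("A", 1, nm)],
            s.coords[s.atom_index("A", 1, nm)], atol=1e-6)
    g = mutate_nucleotide(s, "A", 1, "G")
    # backbone/sugar atoms bit-identical
    for nm in ("C1'", "O3'"):
        np.testing.assert_array_equal(g.coords[g.atom_index("A", 1, nm)],
                                      s.coords[s.atom_index("A", 1, nm)])
    assert {a.name for a in g.atoms} == set(BASE_TEMPLATES["G"]) | {"O3'"}
    assert g.atoms[0].res_name == "G"


def test_purine_to_pyrimidine_frame_superposition():
    s = _toy_nucleotide("G")
    c = mutate_nucleotide(s, "A", 1, "C", tolerance=0.5)
    # shared glycosidic frame: C1' and the glycosidic N position
    old_frame = np.stack([s.coords[s.atom_index("A", 1, "C1'")],
                          s.coords[s.atom_index("A", 1, "N9")]])
    new_frame = np.stack([c.coords[c.atom_index("A", 1, "C1'")],
                          c.coords[c.atom_index("A", 1, "N1")]])
    # C1' identical; glycosidic N within the graft tolerance
    np.testing.assert_array_equal(old_frame[0], new_frame[0])
    assert np.linalg.norm(old_frame[1] - new_frame[1]) < 0.5


def test_mutation_rejects_non_nucleotide(dumbbell):
    start, _, _ = dumbbell
    with pytest.raises(ValueError, match="not a ribonucleotide"):
        mutate_nucleotide(start, "A", 1, "G")


def test_mutation_changes_nothing_outside_target_residue():
    tmpl = BASE_TEMPLATES["A"]
    atoms = [AtomRecord(i + 1, nm, nm[0], "A", 1, "A", xyz.copy())
             for i, (nm, xyz) in enumerate(tmpl.items())]
    off = np.array([20.0, 0.0, 0.0])
    n0 = len(atoms)
    atoms += [AtomRecord(n0 + i + 1, nm, nm[0], "U", 2, "A", xyz + off)
              for i, (nm, xyz) in enumerate(BASE_TEMPLATES["U"].items())]
    s = MolecularStructure(atoms)
    m = mutate_nucleotide(s, "A", 1, "G")
    for nm in BASE_TEMPLATES["U"]:
        np.testing.assert_array_equal(m.coords[m.atom_index("A", 2, nm)],
                                      s.coords[s.atom_index("A", 2, nm)])


def test_measurement_config_resolution(tmp_path, dumbbell):
    import json

    from riboswivel.structure import (
        load_measurement_config, resolve_atom, resolve_selection,
    )

    start, _, _ = dumbbell
    cfg = {
        "head_plane_atoms": [["B", 1, "X1"], ["B", 2, "X1"], ["B", 3, "X1"]],
        "body_core": {"chain": "A", "heavy_only": True},
        "hinge_1": {"chain": "C", "res_range": [1, 2]},
    }
    p = tmp_path / "measure.json"
    p.write_text(json.dumps(cfg))
    loaded = load_measurement_config(p)
    idx = [resolve_atom(start, ref) for ref in loaded["head_plane_atoms"]]
    assert len(set(idx)) == 3
    assert all(start.atoms[i].chain_id == "B" for i in idx)
    body = resolve_selection(start, loaded["body_core"])
    assert all(start.atoms[i].chain_id == "A" for i in body.indices)
    hinge = resolve_selection(start, loaded["hinge_1"])
    assert {start.atoms[i].res_seq for i in hinge.indices} == {1, 2}
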