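"""Residue chemistry templates.

Bond connectivity for the standard ribonucleotides and amino acids, the
synthetic three-atom "DUM" residue used by the toy generators, idealized
planar base geometries for nucleotide mutation, and the inter-residue
linkage rules (phosphodiester O3'-P, peptide C-N).

Connectivity is standard reference chemistry; the idealized base
coordinates are internally consistent planar geometries (regular fused
rings, 1.38 A ring bonds) built once at import.  They are the geometry
source for both the synthetic duplex generator and the base-swap
operation, so a base grafted onto a frame built from the same template
reproduces it exactly.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# connectivity tables
# ---------------------------------------------------------------------------

RNA_BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
}

_RNA_SUGAR_BONDS = [
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"), ("O5'", "C5'"), ("C5'", "C4'"),
    ("C4'", "O4'"), ("C4'", "C3'"), ("C3'", "O3'"), ("C3'", "C2'"),
    ("C2'", "O2'"), ("C2'", "C1'"), ("C1'", "O4'"),
]

_PURINE_RING_BONDS = [
    ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"), ("C6", "N1"),
    ("C4", "N9"), ("N9", "C8"), ("C8", "N7"), ("N7", "C5"),
]
_PYRIMIDINE_RING_BONDS = [
    ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"), ("C6", "N1"),
]

_BASE_BONDS = {
    "A": _PURINE_RING_BONDS + [("C6", "N6"), ("C1'", "N9")],
    "G": _PURINE_RING_BONDS + [("C6", "O6"), ("C2", "N2"), ("C1'", "N9")],
    "C": _PYRIMIDINE_RING_BONDS + [("C2", "O2"), ("C4", "N4"), ("C1'", "N1")],
    "U": _PYRIMIDINE_RING_BONDS + [("C2", "O2"), ("C4", "O4"), ("C1'", "N1")],
}

# sp2 / aromatic atoms: improper-style torsions around these use the
# planar strength rather than the chiral-improper strength
_BASE_PLANAR = {
    "A": {"N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9", "N6"},
    "G": {"N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9", "O6", "N2"},
    "C": {"N1", "C2", "N3", "C4", "C5", "C6", "O2", "N4"},
    "U": {"N1", "C2", "N3", "C4", "C5", "C6", "O2", "O4"},
}

_AA_SIDECHAIN_BONDS = {
    "GLY": [],
    "ALA": [("CA", "CB")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE3", "CZ3"), ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("ND1", "CE1"),
            ("CE1", "NE2"), ("NE2", "CD2"), ("CD2", "CG")],
}

_AA_PLANAR = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "ASP": {"CG"},
    "GLU": {"CD"},
    "ASN": {"CG"},
    "GLN": {"CD"},
    "ARG": {"CZ", "NE"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}


class ResidueTemplate:
    """Connectivity (and optional planarity flags) for one residue type."""

    def __init__(self, name, bonds, backbone, planar=(), link=None):
        self.name = name
        self.bonds = list(bonds)
        self.backbone = set(backbone)
        self.planar = set(planar)
        # link: (atom in previous residue, atom in this residue)
        self.link = link


_REGISTRY: dict[str, ResidueTemplate] = {}


def _register(t: ResidueTemplate) -> None:
    _REGISTRY[t.name] = t


for _b in "ACGU":
    _register(
        ResidueTemplate(
            _b,
            _RNA_SUGAR_BONDS + _BASE_BONDS[_b],
            RNA_BACKBONE_ATOMS,
            planar=_BASE_PLANAR[_b],
            link=("O3'", "P"),
        )
    )

for _aa, _sc in _AA_SIDECHAIN_BONDS.items():
    _register(
        ResidueTemplate(
            _aa,
            [("N", "CA"), ("CA", "C"), ("C", "O")] + _sc,
            {"N", "CA", "C", "O"},
            planar={"C"} | _AA_PLANAR.get(_aa, set()),
            link=("C", "N"),
        )
    )

# three-atom synthetic residue used by the toy structure generators
_register(
    ResidueTemplate(
        "DUM",
        [("X1", "X2"), ("X2", "X3")],
        {"X1", "X2", "X3"},
        link=("X3", "X1"),
    )
)


def get_template(res_name: str) -> ResidueTemplate:
    try:
        return _REGISTRY[res_name.strip()]
    except KeyError:
        raise KeyError(
            f"no residue template for {res_name!r}; known: {sorted(_REGISTRY)}"
        ) from None


def has_template(res_name: str) -> bool:
    return res_name.strip() in _REGISTRY


# ---------------------------------------------------------------------------
# idealized base geometry (planar, local frame)
# ---------------------------------------------------------------------------

_RING_BOND = 1.38  # A, aromatic ring bond
_EXO_BOND = 1.35   # A, exocyclic C-O / C-N
_GLYCO_BOND = 1.47  # A, C1'-N glycosidic


def _regular_polygon(names, side):
    """Atoms of a regular polygon in the xy-plane, first edge centered."""
    n = len(names)
    r = side / (2.0 * np.sin(np.pi / n))
    coords = {}
    for i, nm in enumerate(names):
        a = 2.0 * np.pi * i / n
        coords[nm] = np.array([r * np.cos(a), r * np.sin(a), 0.0])
    return coords


def _exocyclic(coords, center, angle_refs, length):
    """Place an atom on the external bisector at ``center``."""
    c = coords[center]
    bisect = sum(c - coords[r] for r in angle_refs)
    bisect = bisect / np.linalg.norm(bisect)
    return c + length * bisect


def _build_base(kind: str) -> dict[str, np.ndarray]:
    if kind in ("A", "G"):
        six = _regular_polygon(["N1", "C2", "N3", "C4", "C5", "C6"], _RING_BOND)
        # fuse the five-ring on the C4-C5 edge, on the outside of the hexagon
        c4, c5 = six["C4"], six["C5"]
        mid = 0.5 * (c4 + c5)
        out = mid / np.linalg.norm(mid)
        # regular pentagon sharing the C4-C5 edge
        r5 = _RING_BOND / (2.0 * np.sin(np.pi / 5))
        center5 = mid + out * (_RING_BOND / (2.0 * np.tan(np.pi / 5)))
        coords = dict(six)
        # remaining three pentagon vertices: N9 (bonded to C4), C8, N7 (bonded to C5)
        ang_c4 = np.arctan2((c4 - center5)[1], (c4 - center5)[0])
        ang_c5 = np.arctan2((c5 - center5)[1], (c5 - center5)[0])
        # step direction from C4 away from C5
        step = 2.0 * np.pi / 5
        d = np.sign(((ang_c4 - ang_c5 + np.pi) % (2 * np.pi)) - np.pi)
        for i, nm in enumerate(["N9", "C8", "N7"], start=1):
            a = ang_c4 + d * step * i
            coords[nm] = center5 + r5 * np.array([np.cos(a), np.sin(a), 0.0])
        if kind == "A":
            coords["N6"] = _exocyclic(coords, "C6", ["N1", "C5"], _EXO_BOND)
        else:
            coords["O6"] = _exocyclic(coords, "C6", ["N1", "C5"], _EXO_BOND)
            coords["N2"] = _exocyclic(coords, "C2", ["N1", "N3"], _EXO_BOND)
        coords["C1'"] = _exocyclic(coords, "N9", ["C4", "C8"], _GLYCO_BOND)
    else:
        coords = _regular_polygon(["N1", "C2", "N3", "C4", "C5", "C6"], _RING_BOND)
        coords["O2"] = _exocyclic(coords, "C2", ["N1", "N3"], _EXO_BOND)
        if kind == "C":
            coords["N4"] = _exocyclic(coords, "C4", ["N3", "C5"], _EXO_BOND)
        else:
            coords["O4"] = _exocyclic(coords, "C4", ["N3", "C5"], _EXO_BOND)
        coords["C1'"] = _exocyclic(coords, "N1", ["C2", "C6"], _GLYCO_BOND)
    return coords


BASE_TEMPLATES: dict[str, dict[str, np.ndarray]] = {b: _build_base(b) for b in "ACGU"}

#: glycosidic nitrogen per base
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}

#: graft frame: C1', glycosidic N, then its two ring neighbours in a fixed
#: role order (ring-junction side first) so purine/pyrimidine frames map
#: onto each other
GRAFT_FRAME = {
    "A": ["C1'", "N9", "C4", "C8"],
    "G": ["C1'", "N9", "C4", "C8"],
    "C": ["C1'", "N1", "C2", "C6"],
    "U": ["C1'", "N1", "C2", "C6"],
}

#: atoms replaced by a base swap (everything that is not backbone/sugar)
def base_atom_names(kind: str) -> list[str]:
    return [nm for nm in BASE_TEMPLATES[kind] if nm != "C1'"]
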