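"""All-atom structure container, PDB I/O, selections and base swapping.

The in-memory model is an ordered list of :class:`AtomRecord` with chain
and residue indexes; PDB reading and writing goes through ``biotite``
(highest-occupancy altloc conformer kept on read).  Residue numbering is
taken verbatim from the source file; measurement targets such as "A977 P"
are resolved as explicit (chain, res_seq, atom name) triples supplied by
a measurement config, never guessed from residue names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import templates
from .linalg import kabsch, apply_transform

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "AtomSelection",
    "PDBFormatError",
    "read_pdb",
    "read_pdb_models",
    "write_pdb",
    "select",
    "center_of_mass",
    "mutate_nucleotide",
    "load_measurement_config",
]

#: element masses (u) for the ``element`` mass scheme
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "MG": 24.305, "K": 39.098, "ZN": 65.38, "X": 12.011,
}


class PDBFormatError(ValueError):
    """Raised when a PDB file cannot be parsed; names the offending line."""


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.serial, self.name, self.element, self.res_name,
                          self.res_seq, self.chain_id, self.coords.copy())


class MolecularStructure:
    """Ordered all-atom model with chain and residue indexes.

    Invariants enforced at construction: at least one atom,
    (chain, res_seq, atom name) unique, and all atoms of a residue
    contiguous in the ordered atom list.
    """

    def __init__(self, atoms: list[AtomRecord]):
        if not atoms:
            raise ValueError("structure must contain at least one atom")
        self.atoms = list(atoms)
        self._build_indexes()

    def _build_indexes(self):
        self.chain_index: dict[str, tuple[int, int]] = {}
        self.residue_index: dict[tuple[str, int], tuple[int, int]] = {}
        seen_keys = set()
        prev_res = None
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.res_seq, a.name)
            if key in seen_keys:
                raise ValueError(f"duplicate atom {key}")
            seen_keys.add(key)
            res = (a.chain_id, a.res_seq)
            if res != prev_res:
                if res in self.residue_index:
                    raise ValueError(f"residue {res} atoms are not contiguous")
                self.residue_index[res] = (i, i + 1)
                prev_res = res
            else:
                s, _ = self.residue_index[res]
                self.residue_index[res] = (s, i + 1)
            if a.chain_id not in self.chain_index:
                self.chain_index[a.chain_id] = (i, i + 1)
            else:
                s, e = self.chain_index[a.chain_id]
                self.chain_index[a.chain_id] = (min(s, i), max(e, i + 1))
        self._coords = np.array([a.coords for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in A (a view of the internal copy)."""
        return self._coords

    def with_coords(self, coords: np.ndarray) -> "MolecularStructure":
        """Copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        new = [AtomRecord(a.serial, a.name, a.element, a.res_name, a.res_seq,
                          a.chain_id, coords[i]) for i, a in enumerate(self.atoms)]
        return MolecularStructure(new)

    def residue_names(self) -> dict[tuple[str, int], str]:
        return {res: self.atoms[s].res_name for res, (s, _) in self.residue_index.items()}

    def chains(self) -> list[str]:
        return list(self.chain_index)

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if not a.is_hydrogen], dtype=int)

    def atom_index(self, chain_id: str, res_seq: int, name: str) -> int:
        s, e = self.residue_index[(chain_id, res_seq)]
        for i in range(s, e):
            if self.atoms[i].name == name:
                return i
        raise KeyError(f"no atom {name!r} in residue ({chain_id}, {res_seq})")


@dataclass
class AtomSelection:
    """Ordered subset of a structure's atoms (strictly increasing indices)."""

    parent: MolecularStructure
    indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices):
            if np.any(np.diff(self.indices) <= 0):
                raise ValueError("selection indices must be strictly increasing")
            if self.indices[0] < 0 or self.indices[-1] >= len(self.parent):
                raise ValueError("selection index out of bounds")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def coords(self) -> np.ndarray:
        return self.parent.coords[self.indices]

    def atoms(self) -> list[AtomRecord]:
        return [self.parent.atoms[i] for i in self.indices]


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _structure_from_atom_array(arr) -> MolecularStructure:
    import biotite.structure as struc

    atoms = []
    n = arr.array_length()
    serials = (arr.get_annotation("atom_id") if "atom_id" in arr.get_annotation_categories()
               else np.arange(1, n + 1))
    for i in range(n):
        elem = str(arr.element[i]).strip() or str(arr.atom_name[i]).strip()[0]
        atoms.append(AtomRecord(
            serial=int(serials[i]),
            name=str(arr.atom_name[i]).strip(),
            element=elem,
            res_name=str(arr.res_name[i]).strip(),
            res_seq=int(arr.res_id[i]),
            chain_id=str(arr.chain_id[i]).strip() or "A",
            coords=np.array(arr.coord[i], dtype=float),
        ))
    return MolecularStructure(atoms)


def _diagnose_bad_line(path) -> str:
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        return f"unparseable coordinate field at line {ln}: {line.rstrip()!r}"
    return "malformed ATOM/HETATM record"


def read_pdb(path) -> MolecularStructure:
    """Read the first model of a PDB file (highest-occupancy altlocs kept)."""
    from biotite.structure.io.pdb import PDBFile

    try:
        pf = PDBFile.read(str(path))
        arr = pf.get_structure(model=1, altloc="occupancy", extra_fields=["atom_id"])
    except Exception as exc:  # noqa: BLE001 - re-raised with line diagnosis
        raise PDBFormatError(f"{path}: {_diagnose_bad_line(path)} ({exc})") from exc
    if arr.array_length() == 0:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records")
    return _structure_from_atom_array(arr)


def read_pdb_models(path) -> list[MolecularStructure]:
    """Read every MODEL block of a multi-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    try:
        pf = PDBFile.read(str(path))
        stack = pf.get_structure(altloc="occupancy", extra_fields=["atom_id"])
    except Exception as exc:  # noqa: BLE001
        raise PDBFormatError(f"{path}: {_diagnose_bad_line(path)} ({exc})") from exc
    if stack.array_length() == 0 or stack.stack_depth() == 0:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records")
    return [_structure_from_atom_array(stack[m]) for m in range(stack.stack_depth())]


def _to_atom_array(structure: MolecularStructure, coords: np.ndarray | None = None):
    import biotite.structure as struc

    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords if coords is not None else structure.coords, dtype=np.float32)
    arr.chain_id = np.array([a.chain_id for a in structure.atoms])
    arr.res_id = np.array([a.res_seq for a in structure.atoms])
    arr.res_name = np.array([a.res_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element.upper() for a in structure.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("atom_id", np.array([a.serial for a in structure.atoms]))
    return arr


def write_pdb(structure: MolecularStructure, path, frames: np.ndarray | None = None) -> None:
    """Write a structure (or a multi-model stack if ``frames`` given) as PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pf = PDBFile()
    if frames is None:
        pf.set_structure(_to_atom_array(structure))
    else:
        frames = np.asarray(frames, dtype=float)
        stack = struc.stack([_to_atom_array(structure, f) for f in frames])
        pf.set_structure(stack)
    pf.write(str(path))


# ---------------------------------------------------------------------------
# selection / measurement helpers
# ---------------------------------------------------------------------------

def select(
    structure: MolecularStructure,
    chain: str | None = None,
    res_seq: int | tuple[int, int] | None = None,
    atom_names=None,
    heavy_only: bool = False,
) -> AtomSelection:
    """Select atoms matching the conjunction of the given predicates.

    ``res_seq`` may be a single residue number or an inclusive
    ``(lo, hi)`` range.  An empty result raises, naming the predicate
    that failed to match, so a measurement can never silently operate on
    zero atoms.
    """
    if len(structure) == 0:
        raise ValueError("cannot select from an empty structure")
    names = set(atom_names) if atom_names is not None else None
    if res_seq is not None and not isinstance(res_seq, tuple):
        res_range = (int(res_seq), int(res_seq))
    else:
        res_range = res_seq
    idx = []
    for i, a in enumerate(structure.atoms):
        if chain is not None and a.chain_id != chain:
            continue
        if res_range is not None and not (res_range[0] <= a.res_seq <= res_range[1]):
            continue
        if names is not None and a.name not in names:
            continue
        if heavy_only and a.is_hydrogen:
            continue
        idx.append(i)
    if not idx:
        preds = []
        if chain is not None:
            preds.append(f"chain={chain!r}")
        if res_range is not None:
            preds.append(f"res_seq={res_range}")
        if names is not None:
            preds.append(f"atom_names={sorted(names)}")
        if heavy_only:
            preds.append("heavy_only")
        raise ValueError("empty selection: no atom matches " + " & ".join(preds or ["<all>"]))
    return AtomSelection(structure, np.array(idx, dtype=int))


def center_of_mass(selection: AtomSelection, mass_scheme: str = "uniform") -> np.ndarray:
    """Mass-weighted mean coordinate of a selection (``uniform`` or ``element``)."""
    if len(selection) == 0:
        raise ValueError("center of mass of an empty selection")
    if mass_scheme == "uniform":
        w = np.ones(len(selection))
    elif mass_scheme == "element":
        w = np.array([ELEMENT_MASSES.get(a.element.upper(), 12.011) for a in selection.atoms()])
    else:
        raise ValueError(f"unknown mass scheme {mass_scheme!r}")
    w = w / w.sum()
    return w @ selection.coords


# ---------------------------------------------------------------------------
# nucleotide mutation (idealized-template base swap)
# ---------------------------------------------------------------------------

def mutate_nucleotide(
    structure: MolecularStructure,
    chain: str,
    res_seq: int,
    new_base: str,
    tolerance: float = 0.5,
) -> MolecularStructure:
    """Swap the base of a ribonucleotide for an idealized template base.

    Backbone and ribose atoms are untouched; base atoms are replaced by
    the idealized ``new_base`` template superposed on the shared
    glycosidic frame (C1', glycosidic N and its two ring neighbours).  A
    frame-superposition residual above ``tolerance`` (A RMSD) aborts.
    """
    new_base = new_base.upper()
    if new_base not in templates.BASE_TEMPLATES:
        raise ValueError(f"unknown base {new_base!r}; expected one of A, C, G, U")
    try:
        s, e = structure.residue_index[(chain, res_seq)]
    except KeyError:
        raise KeyError(f"no residue ({chain!r}, {res_seq})") from None
    old_base = structure.atoms[s].res_name.strip()
    if old_base not in templates.BASE_TEMPLATES:
        raise ValueError(f"residue ({chain!r}, {res_seq}) is {old_base!r}, not a ribonucleotide")

    res_atoms = {a.name: a for a in structure.atoms[s:e]}
    old_frame_names = templates.GRAFT_FRAME[old_base]
    missing = [nm for nm in old_frame_names if nm not in res_atoms]
    if missing:
        raise ValueError(f"residue ({chain!r}, {res_seq}) lacks frame atoms {missing}")
    frame_target = np.array([res_atoms[nm].coords for nm in old_frame_names])

    tmpl = templates.BASE_TEMPLATES[new_base]
    new_frame_names = templates.GRAFT_FRAME[new_base]
    frame_mobile = np.array([tmpl[nm] for nm in new_frame_names])
    R, t, rmsd = kabsch(frame_mobile, frame_target)
    if rmsd > tolerance:
        raise ValueError(
            f"glycosidic-frame superposition residual {rmsd:.3f} A exceeds tolerance {tolerance} A"
        )

    old_base_names = set(templates.base_atom_names(old_base))
    new_names = templates.base_atom_names(new_base)
    kept = [a.copy() for a in structure.atoms[s:e] if a.name not in old_base_names]
    grafted = [
        AtomRecord(0, nm, nm[0], new_base, res_seq, chain, apply_transform(tmpl[nm], R, t))
        for nm in new_names
    ]
    new_res = kept + grafted
    for a in new_res:
        a.res_name = new_base

    out = [a.copy() for a in structure.atoms[:s]] + new_res + [a.copy() for a in structure.atoms[e:]]
    for i, a in enumerate(out):
        a.serial = i + 1
    return MolecularStructure(out)


# ---------------------------------------------------------------------------
# measurement config
# ---------------------------------------------------------------------------

def load_measurement_config(path) -> dict:
    """Load a JSON/YAML measurement config.

    The config maps logical names used by the measurement layer
    ("head_plane_atoms", "body_core", "E_loop", ...) to atom references.
    An atom reference is a ``[chain, res_seq, atom_name]`` triple; a
    selection is either a list of triples or a
    ``{"chain": ..., "res_range": [lo, hi], "atom_names": [...]}`` object.
    """
    text = open(path).read()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        import yaml

        return yaml.safe_load(text)


def resolve_atom(structure: MolecularStructure, ref) -> int:
    """Resolve a [chain, res_seq, atom_name] triple to an atom index."""
    chain, res_seq, name = ref
    return structure.atom_index(str(chain), int(res_seq), str(name))


def resolve_selection(structure: MolecularStructure, spec) -> AtomSelection:
    """Resolve a config selection (triple list or range object)."""
    if isinstance(spec, dict):
        rng = spec.get("res_range")
        return select(
            structure,
            chain=spec.get("chain"),
            res_seq=tuple(rng) if rng else None,
            atom_names=spec.get("atom_names"),
            heavy_only=bool(spec.get("heavy_only", False)),
        )
    idx = sorted(resolve_atom(structure, ref) for ref in spec)
    return AtomSelection(structure, np.array(idx, dtype=int))
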