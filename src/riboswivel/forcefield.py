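"""Structure-based ("Go"-type) all-atom potential.

The potential has a single global minimum at the reference (native)
structure:

* harmonic bonds, bend angles and improper/planar torsions about their
  native values,
* cosine ("FD") proper dihedrals about native values,
  FD(d) = [1 - cos d] + 1/2 [1 - cos 3d],
* attractive 12-6 wells for native contacts (heavy-atom pairs within
  4 A in the reference, minus bonded and sequence-adjacent pairs),
* a purely repulsive r^-12 excluded volume for everything else.

Reduced units: energies in eps0 = 1, the Boltzmann constant is 1.
Default strengths: eps_r = 50, eps_theta = 40, eps_chi_improper = 10,
eps_chi_planar = 40, eps_NC = 0.1, sigma_NC = 2.5 A.

Contact-group rescaling reflects the translocation setup: substrate
(tRNA/mRNA)-ribosome contacts x0.6, small-subunit head-body interface
x0.3, intersubunit contacts x0.3 within 20 A of the core and x0.1
outside, EF-G contacts x0.6.  A second conformation can be merged in as
an additional energy basin by appending its unique contacts
(:func:`merge_basins`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import templates
from .linalg import bond_lengths, bend_angles, dihedral_angles
from .structure import MolecularStructure

__all__ = [
    "ForceFieldParameters",
    "BondedTerms",
    "ContactSet",
    "ScalingScheme",
    "ForceField",
    "find_contacts",
    "apply_scaling",
    "build_forcefield",
    "merge_basins",
    "dihedral_FD",
]


@dataclass
class ForceFieldParameters:
    """Reduced-unit strengths of the potential terms."""

    eps0: float = 1.0
    eps_r: float = 50.0
    eps_theta: float = 40.0
    eps_chi_improper: float = 10.0
    eps_chi_planar: float = 40.0
    eps_NC: float = 0.1
    sigma_NC: float = 2.5
    eps_BB: float = 1.0
    eps_SC: float = 0.5
    contact_cutoff: float = 4.0

    def __post_init__(self):
        for nm in ("eps_r", "eps_theta", "eps_chi_improper", "eps_chi_planar",
                   "eps_NC", "sigma_NC", "eps_BB", "eps_SC", "contact_cutoff"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")


@dataclass
class BondedTerms:
    """Index tuples and native reference values for the bonded sums."""

    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    bonds_r0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    angles_t0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    impropers: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))
    impropers_x0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    planars: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))
    planars_x0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedrals: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))
    dihedrals_p0: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedrals_backbone: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def pair_set(self) -> set[tuple[int, int]]:
        """All atom pairs appearing together in any bonded term."""
        pairs: set[tuple[int, int]] = set()
        for idx in (self.bonds, self.angles, self.impropers, self.planars, self.dihedrals):
            for row in idx:
                row = sorted(int(v) for v in row)
                for a in range(len(row)):
                    for b in range(a + 1, len(row)):
                        pairs.add((row[a], row[b]))
        return pairs


@dataclass
class ContactSet:
    """Native-contact pairs with well widths, depths and group/basin labels."""

    pairs: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    sigma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    eps: np.ndarray = field(default_factory=lambda: np.zeros(0))
    group: list[str] = field(default_factory=list)
    basin: list[str] = field(default_factory=list)
    scaled: bool = False

    def __len__(self) -> int:
        return len(self.pairs)

    def copy(self) -> "ContactSet":
        return ContactSet(self.pairs.copy(), self.sigma.copy(), self.eps.copy(),
                          list(self.group), list(self.basin), self.scaled)


@dataclass
class ScalingScheme:
    """Contact-group rescaling factors and group membership.

    ``groups`` maps a group name (``SSU_head``, ``SSU_body``, ``LSU``,
    ``tRNA``, ``mRNA``, ``EFG``) to a list of ``(chain, lo, hi)`` residue
    ranges (``lo``/``hi`` may be ``None`` for a whole chain).  Every atom
    participating in a contact must fall in exactly one group.
    """

    substrate_scale: float = 0.6
    head_body_scale: float = 0.3
    intersubunit_core_scale: float = 0.3
    intersubunit_far_scale: float = 0.1
    core_radius: float = 20.0
    efg_scale: float = 0.6
    groups: dict[str, list[tuple]] = field(default_factory=dict)
    core_point: np.ndarray | None = None

    SUBSTRATE = ("tRNA", "mRNA")
    SSU = ("SSU_head", "SSU_body")

    def __post_init__(self):
        for nm in ("substrate_scale", "head_body_scale", "intersubunit_core_scale",
                   "intersubunit_far_scale", "efg_scale"):
            v = getattr(self, nm)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{nm} must be in (0, 1]")

    def atom_groups(self, structure: MolecularStructure) -> list[str | None]:
        out: list[str | None] = [None] * len(structure)
        for gname, ranges in self.groups.items():
            for rng in ranges:
                chain, lo, hi = (rng if len(rng) == 3 else (rng[0], None, None))
                for i, a in enumerate(structure.atoms):
                    if a.chain_id != chain:
                        continue
                    if lo is not None and not (lo <= a.res_seq <= hi):
                        continue
                    if out[i] is not None and out[i] != gname:
                        raise ValueError(f"atom {i} assigned to both {out[i]} and {gname}")
                    out[i] = gname
        return out


def dihedral_FD(phi, phi0=0.0):
    """Cosine dihedral shape FD(d) = [1 - cos d] + 1/2 [1 - cos 3d], d = phi - phi0."""
    d = np.asarray(phi, dtype=float) - phi0
    return (1.0 - np.cos(d)) + 0.5 * (1.0 - np.cos(3.0 * d))


def dihedral_FD_prime(phi, phi0=0.0):
    d = np.asarray(phi, dtype=float) - phi0
    return np.sin(d) + 1.5 * np.sin(3.0 * d)


@dataclass
class ForceField:
    """Complete term set of the potential for one reference structure."""

    parameters: ForceFieldParameters
    bonded: BondedTerms
    contacts: ContactSet
    n_atoms: int
    heavy: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    noncontact_pairs: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))

    def rebuild_noncontacts(self) -> None:
        """Excluded-volume pair list: heavy pairs not in bonded terms or contacts."""
        excluded = self.bonded.pair_set()
        for (i, j) in self.contacts.pairs:
            excluded.add((min(int(i), int(j)), max(int(i), int(j))))
        heavy = set(int(i) for i in self.heavy)
        pairs = []
        hs = sorted(heavy)
        for ai in range(len(hs)):
            for bi in range(ai + 1, len(hs)):
                p = (hs[ai], hs[bi])
                if p not in excluded:
                    pairs.append(p)
        self.noncontact_pairs = (np.array(pairs, dtype=np.int64)
                                 if pairs else np.zeros((0, 2), dtype=np.int64))

    # -- serialization ------------------------------------------------------

    def to_file(self, path) -> None:
        """Write a plain-text topology: term lists with reference values."""
        p = self.parameters
        with open(path, "w") as fh:
            fh.write("# riboswivel structure-based forcefield topology\n")
            fh.write(f"# reduced units; eps_BB={p.eps_BB:.9g} eps_SC={p.eps_SC:.9g}\n")
            fh.write(f"params {p.eps0} {p.eps_r} {p.eps_theta} {p.eps_chi_improper} "
                     f"{p.eps_chi_planar} {p.eps_NC} {p.sigma_NC} {p.eps_BB} {p.eps_SC} "
                     f"{p.contact_cutoff}\n")
            fh.write(f"n_atoms {self.n_atoms}\n")
            fh.write("heavy " + " ".join(map(str, self.heavy.tolist())) + "\n")
            b = self.bonded
            for name, idx, ref in (
                ("bond", b.bonds, b.bonds_r0), ("angle", b.angles, b.angles_t0),
                ("improper", b.impropers, b.impropers_x0), ("planar", b.planars, b.planars_x0),
            ):
                for row, r0 in zip(idx, ref):
                    fh.write(f"{name} " + " ".join(map(str, row.tolist())) + f" {r0:.12g}\n")
            for row, p0, bb in zip(b.dihedrals, b.dihedrals_p0, b.dihedrals_backbone):
                cls = "backbone" if bb else "sidechain"
                fh.write("dihedral " + " ".join(map(str, row.tolist())) + f" {p0:.12g} {cls}\n")
            c = self.contacts
            fh.write(f"contacts_scaled {int(c.scaled)}\n")
            for (i, j), s, e, g, bl in zip(c.pairs, c.sigma, c.eps, c.group, c.basin):
                fh.write(f"contact {i} {j} {s:.12g} {e:.12g} {g} {bl}\n")

    @classmethod
    def from_file(cls, path) -> "ForceField":
        params = None
        n_atoms = 0
        heavy = np.zeros(0, dtype=np.int64)
        rows: dict[str, list] = {k: [] for k in
                                 ("bond", "angle", "improper", "planar", "dihedral", "contact")}
        scaled = False
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                tok = line.split()
                if tok[0] == "params":
                    v = list(map(float, tok[1:]))
                    params = ForceFieldParameters(*v)
                elif tok[0] == "n_atoms":
                    n_atoms = int(tok[1])
                elif tok[0] == "heavy":
                    heavy = np.array(list(map(int, tok[1:])), dtype=np.int64)
                elif tok[0] == "contacts_scaled":
                    scaled = bool(int(tok[1]))
                elif tok[0] in rows:
                    rows[tok[0]].append(tok[1:])
        def _terms(key, nidx):
            data = rows[key]
            if not data:
                return (np.zeros((0, nidx), dtype=np.int64), np.zeros(0))
            idx = np.array([[int(v) for v in r[:nidx]] for r in data], dtype=np.int64)
            ref = np.array([float(r[nidx]) for r in data])
            return idx, ref
        bonds, bonds_r0 = _terms("bond", 2)
        angles, angles_t0 = _terms("angle", 3)
        imps, imps_x0 = _terms("improper", 4)
        plns, plns_x0 = _terms("planar", 4)
        dih = rows["dihedral"]
        if dih:
            d_idx = np.array([[int(v) for v in r[:4]] for r in dih], dtype=np.int64)
            d_p0 = np.array([float(r[4]) for r in dih])
            d_bb = np.array([r[5] == "backbone" for r in dih], dtype=bool)
        else:
            d_idx = np.zeros((0, 4), dtype=np.int64)
            d_p0 = np.zeros(0)
            d_bb = np.zeros(0, dtype=bool)
        con = rows["contact"]
        if con:
            c_pairs = np.array([[int(r[0]), int(r[1])] for r in con], dtype=np.int64)
            c_sigma = np.array([float(r[2]) for r in con])
            c_eps = np.array([float(r[3]) for r in con])
            c_grp = [r[4] for r in con]
            c_bas = [r[5] for r in con]
        else:
            c_pairs = np.zeros((0, 2), dtype=np.int64)
            c_sigma = np.zeros(0)
            c_eps = np.zeros(0)
            c_grp, c_bas = [], []
        ff = cls(
            parameters=params or ForceFieldParameters(),
            bonded=BondedTerms(bonds, bonds_r0, angles, angles_t0, imps, imps_x0,
                               plns, plns_x0, d_idx, d_p0, d_bb),
            contacts=ContactSet(c_pairs, c_sigma, c_eps, c_grp, c_bas, scaled),
            n_atoms=n_atoms,
            heavy=heavy,
        )
        ff.rebuild_noncontacts()
        return ff


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

#: terms are dropped when their reference geometry is within this angle
#: (radians) of collinear
COLLINEAR_TOL = 0.1


def _torsion_well_conditioned(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """True where both inner bend angles of a torsion are away from collinear."""
    s = np.sin(COLLINEAR_TOL)
    ok = np.ones(len(idx), dtype=bool)
    for cols in ((0, 1, 2), (1, 2, 3)):
        u = coords[idx[:, cols[0]]] - coords[idx[:, cols[1]]]
        v = coords[idx[:, cols[2]]] - coords[idx[:, cols[1]]]
        cr = np.linalg.norm(np.cross(u, v), axis=1)
        ok &= cr / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)) > s
    return ok


def _bond_graph(structure: MolecularStructure) -> list[tuple[int, int]]:
    """Covalent bonds from residue templates + inter-residue links."""
    bonds: list[tuple[int, int]] = []
    res_keys = list(structure.residue_index)
    for (chain, res_seq) in res_keys:
        s, e = structure.residue_index[(chain, res_seq)]
        res_name = structure.atoms[s].res_name
        tmpl = templates.get_template(res_name)
        present = {structure.atoms[i].name: i for i in range(s, e)}
        for a, b in tmpl.bonds:
            if a in present and b in present:
                bonds.append((present[a], present[b]))
        # link to the previous residue in the same chain if contiguous numbering
        prev = (chain, res_seq - 1)
        if tmpl.link and prev in structure.residue_index:
            ps, pe = structure.residue_index[prev]
            prev_present = {structure.atoms[i].name: i for i in range(ps, pe)}
            la, lb = tmpl.link
            if la in prev_present and lb in present:
                bonds.append((prev_present[la], present[lb]))
    return [(min(i, j), max(i, j)) for i, j in bonds]


def _enumerate_bonded(structure: MolecularStructure) -> BondedTerms:
    coords = structure.coords
    bond_pairs = sorted(set(_bond_graph(structure)))
    adj: dict[int, list[int]] = {}
    for i, j in bond_pairs:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    for v in adj.values():
        v.sort()

    angles = []
    for j in sorted(adj):
        nb = adj[j]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))

    dihedrals = []
    for j, k in bond_pairs:
        for i in adj.get(j, []):
            if i == k:
                continue
            for l in adj.get(k, []):
                if l == j or l == i:
                    continue
                quad = (i, j, k, l)
                if quad[::-1] < quad:
                    quad = quad[::-1]
                dihedrals.append(quad)
    dihedrals = sorted(set(dihedrals))

    # torsions around 3-coordinated centers keep chirality (sp3) or
    # planarity (sp2, template-flagged)
    impropers, planars = [], []
    planar_atoms = set()
    for (chain, res_seq), (s, e) in structure.residue_index.items():
        tmpl = templates.get_template(structure.atoms[s].res_name)
        for i in range(s, e):
            if structure.atoms[i].name in tmpl.planar:
                planar_atoms.add(i)
    for c in sorted(adj):
        nb = adj[c]
        if len(nb) < 3:
            continue
        quad = (nb[0], nb[1], c, nb[2])
        if c in planar_atoms:
            planars.append(quad)
        else:
            impropers.append(quad)

    def _idx(lst, n):
        return (np.array(lst, dtype=np.int64) if lst else np.zeros((0, n), dtype=np.int64))

    b = BondedTerms(
        bonds=_idx(bond_pairs, 2),
        angles=_idx(angles, 3),
        impropers=_idx(impropers, 4),
        planars=_idx(planars, 4),
        dihedrals=_idx(dihedrals, 4),
    )
    b.bonds_r0 = bond_lengths(coords, b.bonds) if len(b.bonds) else np.zeros(0)

    # regularization: terms whose reference geometry is (near-)collinear
    # have ill-defined angles/torsions and cusp-like gradients; drop them
    # at build time (threshold 0.1 rad from collinearity)
    if len(b.angles):
        t0 = bend_angles(coords, b.angles)
        keep = (t0 > COLLINEAR_TOL) & (t0 < np.pi - COLLINEAR_TOL)
        b.angles = b.angles[keep]
        b.angles_t0 = t0[keep]
    for attr in ("impropers", "planars", "dihedrals"):
        idx = getattr(b, attr)
        if not len(idx):
            continue
        keep = _torsion_well_conditioned(coords, idx)
        idx = idx[keep]
        setattr(b, attr, idx)
        setattr(b, attr + ("_x0" if attr != "dihedrals" else "_p0"),
                dihedral_angles(coords, idx) if len(idx) else np.zeros(0))

    # backbone class: all four atoms are backbone atoms of their residues
    bb_flags = []
    backbone_atoms = set()
    for (chain, res_seq), (s, e) in structure.residue_index.items():
        tmpl = templates.get_template(structure.atoms[s].res_name)
        for i in range(s, e):
            if structure.atoms[i].name in tmpl.backbone:
                backbone_atoms.add(i)
    for quad in b.dihedrals:
        bb_flags.append(all(int(q) in backbone_atoms for q in quad))
    b.dihedrals_backbone = np.array(bb_flags, dtype=bool)
    return b


def find_contacts(
    structure: MolecularStructure,
    cutoff: float = 4.0,
    bonded_pairs: set[tuple[int, int]] | None = None,
) -> ContactSet:
    """Native contacts: heavy-atom pairs within ``cutoff`` in the structure.

    Pairs within one residue, in sequence-adjacent residues of the same
    chain, or appearing in any bonded term (``bonded_pairs``) are
    excluded.  Well width sigma_ij is the observed pair distance; depth
    is initialised to eps0 = 1 for later group scaling.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy = structure.heavy_indices()
    coords = structure.coords[heavy]
    tree = cKDTree(coords)
    raw = tree.query_pairs(r=cutoff, output_type="ndarray")
    pairs, sigma = [], []
    bonded_pairs = bonded_pairs or set()
    for a, b in raw:
        i, j = int(heavy[a]), int(heavy[b])
        if i > j:
            i, j = j, i
        ai, aj = structure.atoms[i], structure.atoms[j]
        if ai.chain_id == aj.chain_id and abs(ai.res_seq - aj.res_seq) <= 1:
            continue
        if (i, j) in bonded_pairs:
            continue
        pairs.append((i, j))
        sigma.append(float(np.linalg.norm(structure.coords[i] - structure.coords[j])))
    order = np.lexsort(
        (np.array([p[1] for p in pairs]), np.array([p[0] for p in pairs]))
    ) if pairs else np.zeros(0, dtype=int)
    pairs_arr = (np.array(pairs, dtype=np.int64)[order]
                 if pairs else np.zeros((0, 2), dtype=np.int64))
    sigma_arr = np.array(sigma)[order] if sigma else np.zeros(0)
    n = len(pairs_arr)
    return ContactSet(pairs_arr, sigma_arr, np.ones(n), ["native"] * n, ["reference"] * n)


def _scale_factor(scheme: ScalingScheme, gi: str, gj: str, midpoint, core) -> float:
    if gi == gj:
        return 1.0
    pair = {gi, gj}
    if "EFG" in pair:
        return scheme.efg_scale
    if pair & set(scheme.SUBSTRATE):
        if pair <= set(scheme.SUBSTRATE):
            return 1.0  # tRNA-mRNA: both substrate, not substrate-ribosome
        return scheme.substrate_scale
    if pair == {"SSU_head", "SSU_body"}:
        return scheme.head_body_scale
    if "LSU" in pair and pair & set(scheme.SSU):
        d = float(np.linalg.norm(np.asarray(midpoint) - np.asarray(core)))
        return (scheme.intersubunit_core_scale if d <= scheme.core_radius
                else scheme.intersubunit_far_scale)
    return 1.0


def apply_scaling(
    contacts: ContactSet,
    scheme: ScalingScheme,
    structure: MolecularStructure,
) -> ContactSet:
    """Rescale contact depths by group-pair factors.

    Each contact's depth is multiplied by the factor selected by its atom
    groups; intersubunit contacts use the core/far scale according to the
    distance of the pair midpoint from the core point.  Rejects contact
    sets that are already scaled.
    """
    if contacts.scaled:
        raise ValueError("contact set already scaled; scaling is applied once")
    groups = scheme.atom_groups(structure)
    core = (scheme.core_point if scheme.core_point is not None
            else structure.coords.mean(axis=0))
    out = contacts.copy()
    new_labels = []
    for n, (i, j) in enumerate(out.pairs):
        gi, gj = groups[int(i)], groups[int(j)]
        if gi is None or gj is None:
            missing = int(i) if gi is None else int(j)
            a = structure.atoms[missing]
            raise ValueError(
                f"atom {missing} ({a.chain_id}/{a.res_seq}/{a.name}) has no group assignment"
            )
        mid = 0.5 * (structure.coords[int(i)] + structure.coords[int(j)])
        out.eps[n] *= _scale_factor(scheme, gi, gj, mid, core)
        new_labels.append(f"{min(gi, gj)}-{max(gi, gj)}")
    out.group = new_labels
    out.scaled = True
    return out


def _normalize_dihedral_strengths(params: ForceFieldParameters,
                                  bonded: BondedTerms,
                                  contacts: ContactSet) -> ForceFieldParameters:
    """SMOG-style budget split: contact:dihedral total 2:1, backbone:sidechain per-term 2:1."""
    n_bb = int(bonded.dihedrals_backbone.sum())
    n_sc = int(len(bonded.dihedrals) - n_bb)
    total_contact = len(contacts) * params.eps0  # pre-scaling depths
    if n_bb + n_sc == 0 or total_contact == 0:
        return params
    budget = total_contact / 2.0
    eps_sc = budget / (2.0 * n_bb + n_sc)
    return replace(params, eps_BB=2.0 * eps_sc, eps_SC=eps_sc)


def build_forcefield(
    reference: MolecularStructure,
    scheme: ScalingScheme | None = None,
    parameters: ForceFieldParameters | None = None,
) -> ForceField:
    """Build the full potential from a reference (native) structure."""
    params = parameters or ForceFieldParameters()
    bonded = _enumerate_bonded(reference)
    contacts = find_contacts(reference, params.contact_cutoff,
                             bonded_pairs=bonded.pair_set())
    params = _normalize_dihedral_strengths(params, bonded, contacts)
    if scheme is not None:
        contacts = apply_scaling(contacts, scheme, reference)
    ff = ForceField(parameters=params, bonded=bonded, contacts=contacts,
                    n_atoms=len(reference), heavy=reference.heavy_indices())
    ff.rebuild_noncontacts()
    return ff


def merge_basins(
    base: ForceField,
    endpoint: MolecularStructure,
    weight: float = 1.0,
    scheme: ScalingScheme | None = None,
) -> ForceField:
    """Append the endpoint conformation's unique contacts as a second basin.

    Contacts present in both conformations keep the starting-basin width
    (the start stays a true minimum); endpoint-unique contacts get width
    from the endpoint geometry and depth ``eps0 * weight`` (then group
    scaling if a scheme is given).  ``weight`` is the global multiplier
    that deepens the endpoint basin.
    """
    if len(endpoint) != base.n_atoms:
        raise ValueError(f"endpoint has {len(endpoint)} atoms, forcefield {base.n_atoms}")
    end_contacts = find_contacts(endpoint, base.parameters.contact_cutoff,
                                 bonded_pairs=base.bonded.pair_set())
    have = {(int(i), int(j)) for i, j in base.contacts.pairs}
    keep = [n for n, (i, j) in enumerate(end_contacts.pairs) if (int(i), int(j)) not in have]
    uniq = ContactSet(
        end_contacts.pairs[keep],
        end_contacts.sigma[keep],
        end_contacts.eps[keep] * float(weight),
        ["native"] * len(keep),
        ["endpoint"] * len(keep),
    )
    if scheme is not None and len(uniq):
        uniq = apply_scaling(uniq, scheme, endpoint)
    merged = ContactSet(
        np.vstack([base.contacts.pairs, uniq.pairs]),
        np.concatenate([base.contacts.sigma, uniq.sigma]),
        np.concatenate([base.contacts.eps, uniq.eps]),
        base.contacts.group + uniq.group,
        base.contacts.basin + uniq.basin,
        base.contacts.scaled,
    )
    ff = ForceField(parameters=base.parameters, bonded=base.bonded, contacts=merged,
                    n_atoms=base.n_atoms, heavy=base.heavy)
    ff.rebuild_noncontacts()
    return ff
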