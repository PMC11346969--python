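"""Synthetic fixtures with known ground truth.

Generators for every input class the pipeline consumes:

* a two-domain "dumbbell" standing in for the small-subunit body/head
  architecture — two jittered-lattice domains joined by hinge strands,
  with an endpoint conformation in which the head is rotated (swivel)
  about the hinge axis and optionally tilted about an in-plane axis;
* an idealized helical duplex (known axis) and a kinked variant for the
  helical-axis and hinge-localization machinery;
* deterministic trajectories with a planted per-frame swivel/tilt
  schedule plus isotropic coordinate noise;
* FASTQ read pools with planted variant frequencies, flanks and phred
  contamination for the enrichment stage.

Everything is bit-reproducible under a fixed seed.  The planted swivel
axis is the normal of the (jittered) measurement plane, so angle
round-trips through the swing--twist measurement are exact by
construction and any residual is measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import Trajectory
from .forcefield import ScalingScheme
from .geometry import ReferenceFrameDefinition
from .linalg import rotation_about_axis
from .structure import AtomRecord, MolecularStructure

__all__ = [
    "DumbbellSpec",
    "SyntheticPoolSpec",
    "make_hinge_dumbbell",
    "dumbbell_scaling_scheme",
    "refdef_from_truth",
    "make_mini_duplex",
    "make_kinked_duplex",
    "make_swivel_trajectory",
    "make_fastq_pools",
]

_L = 3.6  # lattice spacing, A: bonded and contact neighbours both sit here


@dataclass
class DumbbellSpec:
    """Geometry and planted motion of the toy head/body dumbbell."""

    swivel_deg: float = 22.6   # full forward swivel: the INT3-analog endpoint
    tilt_deg: float = 0.0
    jitter: float = 0.1          # A, lattice jitter
    seed: int = 0
    min_separation: float = 1.6  # A, clash threshold after rotation
    max_attempts: int = 20


def _domain_sites(z_layers):
    """Residues of 3 atoms along x, two per row, four rows, hole at the axis.

    The four-row plates put lattice sites on both sides of each rim atom's
    rotation arc, so a swivel of the head by the planted angle breaks
    peripheral interface contacts and forms new ones (the endpoint basin)
    while contacts near the axis survive and act as the pivot.
    """
    sites = []
    for z in z_layers:
        for y in (-_L, 0.0, _L):
            for xs in ((-2.5 * _L, -1.5 * _L, -0.5 * _L), (0.5 * _L, 1.5 * _L, 2.5 * _L)):
                sites.append([(x, y, z) for x in xs])
    return sites


def _linker_sites():
    """Two hinge strands spanning the inter-domain gap near the axis."""
    zs = (-1.25 * _L, -0.75 * _L, -0.25 * _L, 0.25 * _L, 0.75 * _L, 1.25 * _L)
    strands = []
    # zigzag in x so no bonded triple/quad is collinear (well-conditioned
    # angle and torsion references)
    dx = 0.5
    for y0 in (0.5 * _L, -0.5 * _L):
        residues = [
            [((-1) ** k * dx, y0, z) for k, z in enumerate(zs[:3])],
            [((-1) ** k * dx, y0, z) for k, z in enumerate(zs[3:], start=1)],
        ]
        strands.append(residues)
    return strands


def _build_atoms(chains: dict[str, list[list[tuple]]]) -> MolecularStructure:
    atoms = []
    serial = 1
    for chain_id, residues in chains.items():
        for r, res_sites in enumerate(residues, start=1):
            for a, xyz in enumerate(res_sites, start=1):
                atoms.append(AtomRecord(serial, f"X{a}", "C", "DUM", r, chain_id,
                                        np.array(xyz, dtype=float)))
                serial += 1
    return MolecularStructure(atoms)


def make_hinge_dumbbell(spec: DumbbellSpec | None = None):
    """Build the start and swivelled-endpoint dumbbell conformations.

    Returns ``(start, endpoint, truth)`` where ``truth`` records the
    hinge axis, plane-atom triple, core selections, hinge atom indices
    and the planted angles.  The endpoint differs from the start by a
    rigid rotation of the head chain: ``swivel_deg`` about the plane
    normal followed by ``tilt_deg`` about an in-plane axis, both through
    the hinge centre.
    """
    spec = spec or DumbbellSpec()
    rng = np.random.default_rng(spec.seed)
    for attempt in range(spec.max_attempts):
        chains = {
            "A": _domain_sites((-1.5 * _L, -0.5 * _L)),   # body below the gap
            "B": _domain_sites((0.5 * _L, 1.5 * _L)),     # head above the gap
        }
        linkers = _linker_sites()
        chains["C"] = linkers[0]
        chains["D"] = linkers[1]
        start = _build_atoms(chains)
        coords = start.coords + rng.normal(0.0, spec.jitter, size=(len(start), 3))
        start = start.with_coords(coords)

        head = np.array([i for i, a in enumerate(start.atoms) if a.chain_id == "B"])
        body = np.array([i for i, a in enumerate(start.atoms) if a.chain_id == "A"])
        hinge = np.array([i for i, a in enumerate(start.atoms) if a.chain_id in ("C", "D")])

        # measurement plane: three spread atoms of the head's top layer;
        # ordered so the normal points along +z (the translocation sense)
        top = [int(i) for i in head if start.coords[i][2] > 1.2 * _L]
        p1 = min(top, key=lambda i: (start.coords[i][0], start.coords[i][1]))
        p2 = max(top, key=lambda i: np.linalg.norm(start.coords[i] - start.coords[p1]))
        u = start.coords[p2] - start.coords[p1]
        p3 = max(top, key=lambda i: np.linalg.norm(
            np.cross(u, start.coords[i] - start.coords[p1])))
        plane = (p1, p2, p3)
        pc = start.coords[list(plane)]
        normal = np.cross(pc[1] - pc[0], pc[2] - pc[0])
        if normal[2] < 0:
            plane = (p1, p3, p2)
            normal = -normal
        axis = normal / np.linalg.norm(normal)

        # in-plane tilt axis: x-direction orthogonalised against the axis
        tilt_axis = np.array([1.0, 0.0, 0.0])
        tilt_axis -= axis * np.dot(tilt_axis, axis)
        tilt_axis /= np.linalg.norm(tilt_axis)

        center = np.zeros(3)
        R = (rotation_about_axis(tilt_axis, np.radians(spec.tilt_deg))
             @ rotation_about_axis(axis, np.radians(spec.swivel_deg)))
        end_coords = start.coords.copy()
        end_coords[head] = (end_coords[head] - center) @ R.T + center
        endpoint = start.with_coords(end_coords)

        others = np.array([i for i in range(len(start)) if i not in set(head.tolist())])
        from scipy.spatial import cKDTree

        dmin = cKDTree(end_coords[others]).query(end_coords[head], k=1)[0].min()
        if dmin >= spec.min_separation:
            truth = {
                "axis": axis.tolist(),
                "tilt_axis": tilt_axis.tolist(),
                "hinge_center": center.tolist(),
                "swivel_deg": spec.swivel_deg,
                "tilt_deg": spec.tilt_deg,
                "plane_atoms": [int(p) for p in plane],
                "body_core": body.tolist(),
                "head_core": head.tolist(),
                "hinge_atoms": hinge.tolist(),
                "seed": spec.seed,
            }
            return start, endpoint, truth
        rng = np.random.default_rng(spec.seed + 1000 * (attempt + 1))
    raise RuntimeError(f"domains overlap after rotation in {spec.max_attempts} attempts")


def dumbbell_scaling_scheme(**overrides) -> ScalingScheme:
    """Group assignment for the dumbbell: head chain vs body + hinge strands."""
    groups = {
        "SSU_body": [("A", None, None), ("C", None, None), ("D", None, None)],
        "SSU_head": [("B", None, None)],
    }
    return ScalingScheme(groups=groups, **overrides)


def refdef_from_truth(reference: MolecularStructure, truth: dict) -> ReferenceFrameDefinition:
    return ReferenceFrameDefinition(
        reference=reference,
        body_core=np.array(truth["body_core"], dtype=int),
        head_core=np.array(truth["head_core"], dtype=int),
        plane_atoms=tuple(truth["plane_atoms"]),
    )


# ---------------------------------------------------------------------------
# duplex fixtures
# ---------------------------------------------------------------------------

def make_mini_duplex(n_bp: int = 12, rise: float = 2.81, twist_deg: float = 32.7,
                     radius: float = 9.4) -> MolecularStructure:
    """Idealized helical duplex with its axis along z.

    Each residue carries backbone P plus minimal C1'/N9 atoms; strand A
    runs 5'->3' up the axis, strand B antiparallel.
    """
    if n_bp < 4:
        raise ValueError("need at least 4 base pairs")
    tw = np.radians(twist_deg)
    atoms = []
    serial = 1
    for chain, direction, phase in (("A", 1.0, 0.0), ("B", -1.0, np.radians(154.0))):
        for i in range(n_bp):
            ang = direction * (i * tw) + phase
            z = i * rise
            for name, r_cyl, dang in (("P", radius, 0.0), ("C1'", 5.9, 0.25),
                                      ("N9", 4.5, 0.35)):
                a = ang + direction * dang
                atoms.append(AtomRecord(
                    serial, name, name[0], "A", i + 1, chain,
                    np.array([r_cyl * np.cos(a), r_cyl * np.sin(a), z])))
                serial += 1
    return MolecularStructure(atoms)


def make_kinked_duplex(n_bp_per_arm: int = 10, bend_deg: float = 30.0,
                       **duplex_kwargs) -> MolecularStructure:
    """Two straight duplex arms meeting at (180 - bend_deg) degrees.

    Built as one straight duplex of ``2 * n_bp_per_arm`` pairs bent
    symmetrically: each arm is rotated by half the bend about a y-axis
    pivot on the helix axis at the junction.  The symmetric construction
    makes the least-squares alignment against the straight duplex the
    identity, so the axis-displacement profile is an exact V with its
    minimum at the junction.
    """
    straight = make_mini_duplex(2 * n_bp_per_arm, **duplex_kwargs)
    rise = duplex_kwargs.get("rise", 2.81)
    z_pivot = (n_bp_per_arm - 0.5) * rise
    pivot = np.array([0.0, 0.0, z_pivot])
    y_axis = np.array([0.0, 1.0, 0.0])
    coords = straight.coords.copy()
    lower = np.array([i for i, a in enumerate(straight.atoms) if a.res_seq <= n_bp_per_arm])
    upper = np.array([i for i, a in enumerate(straight.atoms) if a.res_seq > n_bp_per_arm])
    R_lo = rotation_about_axis(y_axis, -0.5 * np.radians(bend_deg))
    R_hi = rotation_about_axis(y_axis, 0.5 * np.radians(bend_deg))
    coords[lower] = (coords[lower] - pivot) @ R_lo.T + pivot
    coords[upper] = (coords[upper] - pivot) @ R_hi.T + pivot
    return straight.with_coords(coords)


# ---------------------------------------------------------------------------
# planted trajectories
# ---------------------------------------------------------------------------

def make_swivel_trajectory(
    start: MolecularStructure,
    truth: dict,
    schedule: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Trajectory:
    """Deterministic trajectory with a planted (swivel, tilt) schedule.

    ``schedule`` has shape (F, 2) in degrees; each frame is the start
    structure with the head rigidly rotated accordingly plus isotropic
    Gaussian noise of ``noise_sigma`` A on every atom.
    """
    schedule = np.atleast_2d(np.asarray(schedule, dtype=float))
    if schedule.shape[1] != 2:
        raise ValueError("schedule must be (n_frames, 2): swivel and tilt in degrees")
    rng = np.random.default_rng(seed)
    axis = np.array(truth["axis"])
    tilt_axis = np.array(truth["tilt_axis"])
    center = np.array(truth["hinge_center"])
    head = np.array(truth["head_core"], dtype=int)
    frames = np.empty((len(schedule), len(start), 3))
    for f, (sw, ti) in enumerate(schedule):
        R = (rotation_about_axis(tilt_axis, np.radians(ti))
             @ rotation_about_axis(axis, np.radians(sw)))
        coords = start.coords.copy()
        coords[head] = (coords[head] - center) @ R.T + center
        if noise_sigma > 0:
            coords += rng.normal(0.0, noise_sigma, size=coords.shape)
        frames[f] = coords
    steps = np.arange(len(schedule))
    return Trajectory(frames, steps, steps + 1.0,
                      provenance={"generator": "make_swivel_trajectory", "seed": seed,
                                  "noise_sigma": noise_sigma})


# ---------------------------------------------------------------------------
# FASTQ pools
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPoolSpec:
    """Planted variant frequencies and read geometry for paired pools."""

    variants: list[str] = field(default_factory=lambda: ["ACGTTGCA", "GGTTCCAA"])
    input_freqs: list[float] = field(default_factory=lambda: [0.5, 0.5])
    output_freqs: list[float] = field(default_factory=lambda: [0.8, 0.2])
    depth: int = 10_000
    upstream: str = "TCAGGCATTC"
    downstream: str = "GATCCTAGGC"
    base_phred: int = 38
    low_phred: int = 20
    contamination_rate: float = 0.0
    filler: int = 6
    seed: int = 0

    def __post_init__(self):
        for freqs in (self.input_freqs, self.output_freqs):
            if len(freqs) != len(self.variants):
                raise ValueError("one frequency per variant required")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError("pool frequencies must sum to 1")
        if self.depth < 1:
            raise ValueError("read depth must be >= 1")
        n = len(self.variants[0])
        if any(len(v) != n for v in self.variants):
            raise ValueError("all variants must share one length")


def _pool_records(spec: SyntheticPoolSpec, freqs, rng, tag: str):
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    n_region = len(spec.upstream) + len(spec.variants[0]) + len(spec.downstream)
    choices = rng.choice(len(spec.variants), size=spec.depth, p=freqs)
    records = []
    for r, vi in enumerate(choices):
        fill_l = "".join(rng.choice(list("ACGT"), size=spec.filler))
        fill_r = "".join(rng.choice(list("ACGT"), size=spec.filler))
        seq = fill_l + spec.upstream + spec.variants[vi] + spec.downstream + fill_r
        phred = np.full(len(seq), spec.base_phred, dtype=int)
        if spec.contamination_rate > 0 and rng.random() < spec.contamination_rate:
            pos = spec.filler + rng.integers(0, n_region)
            phred[pos] = spec.low_phred
        rec = SeqRecord(Seq(seq), id=f"{tag}_{r}", description="")
        rec.letter_annotations["phred_quality"] = phred.tolist()
        records.append(rec)
    return records


def make_fastq_pools(spec: SyntheticPoolSpec, input_path, output_path) -> dict:
    """Write input/output FASTQ pools; returns the planted truth table.

    The truth table maps each variant to its planted input and output
    frequencies and expected enrichment (output / input frequency).
    """
    from Bio import SeqIO

    rng = np.random.default_rng(spec.seed)
    for path, freqs, tag in ((input_path, spec.input_freqs, "in"),
                             (output_path, spec.output_freqs, "out")):
        records = _pool_records(spec, freqs, rng, tag)
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fastq")
    return {
        "variants": {
            v: {
                "input_freq": fi,
                "output_freq": fo,
                "expected_enrichment": (fo / fi) if fi > 0 else float("nan"),
            }
            for v, fi, fo in zip(spec.variants, spec.input_freqs, spec.output_freqs)
        },
        "depth": spec.depth,
        "contamination_rate": spec.contamination_rate,
        "seed": spec.seed,
    }
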