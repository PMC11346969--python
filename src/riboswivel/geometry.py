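"""Per-frame structural measurements on trajectories.

Implements the reaction coordinates used to follow small-subunit head
motion during translocation: swivel and tilt of the head relative to the
body (swing--twist decomposition of the head rotation about a reference
plane normal), body rotation relative to the large subunit, per-atom
RMSF, atom-pair and center-of-mass distance series, a sliding-window
helical-axis trace with displacement profiles and hinge (inflection)
localization, and PCA of selected-atom motion.

All angle measurements first remove global motion by superposing the
frame on the reference over a "core" alignment selection, so they are
invariant under rigid motion of the entire complex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter, find_peaks

from .linalg import kabsch, apply_transform, swing_twist, angle_between
from .structure import MolecularStructure

__all__ = [
    "ReferenceFrameDefinition",
    "AngleSeries",
    "FluctuationProfile",
    "HelicalAxisProfile",
    "kabsch_superpose",
    "measure_swivel_tilt",
    "measure_body_rotation",
    "measure_angles_series",
    "rmsf",
    "pair_distance_series",
    "com_distance_series",
    "helix_axis",
    "axis_displacement_profile",
    "locate_hinges",
    "pca_motion",
]


def kabsch_superpose(mobile_coords: np.ndarray, target_coords: np.ndarray):
    """Least-squares rigid superposition; returns (R, t, rmsd)."""
    return kabsch(mobile_coords, target_coords)


@dataclass
class ReferenceFrameDefinition:
    """Alignment cores and plane atoms defining the angle measurements.

    ``plane_atoms`` is an ordered atom-index triple; its cross-product
    normal fixes the swivel axis and the sign convention (positive
    swivel = direction of translocation for the documented atom order).
    """

    reference: MolecularStructure
    body_core: np.ndarray
    head_core: np.ndarray
    plane_atoms: tuple[int, int, int]

    def __post_init__(self):
        self.body_core = np.asarray(self.body_core, dtype=int)
        self.head_core = np.asarray(self.head_core, dtype=int)
        if len(self.body_core) < 3 or len(self.head_core) < 3:
            raise ValueError("alignment cores need at least 3 atoms")
        n = self.plane_normal()
        if np.linalg.norm(n) < 1e-8:
            raise ValueError("plane atoms are collinear in the reference")

    def plane_normal(self) -> np.ndarray:
        p = self.reference.coords[list(self.plane_atoms)]
        n = np.cross(p[1] - p[0], p[2] - p[0])
        nn = np.linalg.norm(n)
        return n / nn if nn > 0 else n


@dataclass
class AngleSeries:
    swivel: np.ndarray
    tilt: np.ndarray
    body_rotation: np.ndarray | None
    time: np.ndarray

    def __post_init__(self):
        if len(self.swivel) != len(self.tilt) or len(self.swivel) != len(self.time):
            raise ValueError("series lengths differ")


@dataclass
class FluctuationProfile:
    atom_indices: np.ndarray
    rmsf: np.ndarray
    region: str = ""


@dataclass
class HelicalAxisProfile:
    points: np.ndarray          # (M, 3) axis points, A
    positions: np.ndarray       # (M,) residue positions attributed to the points
    helix_labels: list[str]     # (M,) source helix of each point


def measure_swivel_tilt(frame_coords: np.ndarray, refdef: ReferenceFrameDefinition):
    """Head swivel and tilt (degrees) of one frame relative to the reference.

    The frame is first aligned to the reference over the body core; the
    residual head rotation (reference head onto aligned frame head) is
    then split by swing--twist decomposition about the reference plane
    normal: the twist component is the swivel, the swing magnitude the
    tilt.  The reference frame itself measures (0, 0).
    """
    ref = refdef.reference.coords
    frame = np.asarray(frame_coords, dtype=float)
    R, t, _ = kabsch(frame[refdef.body_core], ref[refdef.body_core])
    aligned = apply_transform(frame, R, t)
    R_head, _, _ = kabsch(ref[refdef.head_core], aligned[refdef.head_core])
    twist, swing = swing_twist(R_head, refdef.plane_normal())
    return float(np.degrees(twist)), float(np.degrees(swing))


def measure_body_rotation(
    frame_coords: np.ndarray,
    refdef: ReferenceFrameDefinition,
):
    """Rotation (degrees) of the plane normal relative to the reference.

    ``refdef`` here carries the body-rotation construction: ``body_core``
    is the large-subunit core used for alignment and ``plane_atoms`` the
    small-subunit body plane triple.  Returns the angle between the
    reference plane normal and the frame plane normal after alignment.
    """
    ref = refdef.reference.coords
    frame = np.asarray(frame_coords, dtype=float)
    R, t, _ = kabsch(frame[refdef.body_core], ref[refdef.body_core])
    aligned = apply_transform(frame, R, t)
    p_ref = ref[list(refdef.plane_atoms)]
    p_frm = aligned[list(refdef.plane_atoms)]
    n_ref = np.cross(p_ref[1] - p_ref[0], p_ref[2] - p_ref[0])
    n_frm = np.cross(p_frm[1] - p_frm[0], p_frm[2] - p_frm[0])
    if np.linalg.norm(n_frm) < 1e-8:
        raise ValueError("plane atoms are collinear in the frame")
    return float(np.degrees(angle_between(n_ref, n_frm)))


def measure_angles_series(
    frames: np.ndarray,
    times: np.ndarray,
    refdef: ReferenceFrameDefinition,
    body_refdef: ReferenceFrameDefinition | None = None,
) -> AngleSeries:
    """Swivel/tilt (and optionally body rotation) for every frame."""
    sw, ti, br = [], [], []
    for f in frames:
        s, t = measure_swivel_tilt(f, refdef)
        sw.append(s)
        ti.append(t)
        if body_refdef is not None:
            br.append(measure_body_rotation(f, body_refdef))
    return AngleSeries(
        np.array(sw), np.array(ti),
        np.array(br) if body_refdef is not None else None,
        np.asarray(times, dtype=float),
    )


def rmsf(
    frames: np.ndarray,
    selection: np.ndarray,
    align_selection: np.ndarray,
    reference: np.ndarray | None = None,
    region: str = "",
) -> FluctuationProfile:
    """Per-atom root-mean-square fluctuation after per-frame alignment.

    Each frame is superposed on the reference (first frame by default)
    over ``align_selection``; the profile is
    sqrt(<(r_i - <r_i>)^2>) over frames for each selected atom.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = np.asarray(selection, dtype=int)
    asel = np.asarray(align_selection, dtype=int)
    ref = np.asarray(reference, dtype=float) if reference is not None else frames[0]
    aligned = np.empty((frames.shape[0], len(sel), 3))
    for f in range(frames.shape[0]):
        R, t, _ = kabsch(frames[f][asel], ref[asel])
        aligned[f] = apply_transform(frames[f][sel], R, t)
    mean = aligned.mean(axis=0)
    dev = aligned - mean
    msf = np.einsum("fij,fij->i", dev, dev) / frames.shape[0]
    return FluctuationProfile(sel, np.sqrt(msf), region)


def pair_distance_series(frames: np.ndarray, i: int, j: int) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    d = frames[:, i, :] - frames[:, j, :]
    return np.sqrt(np.einsum("ij,ij->i", d, d))


def com_distance_series(
    frames: np.ndarray,
    sel_a: np.ndarray,
    sel_b: np.ndarray,
    weights_a: np.ndarray | None = None,
    weights_b: np.ndarray | None = None,
) -> np.ndarray:
    """Distance between the centers of mass of two selections per frame."""
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("center-of-mass distance of an empty selection")
    frames = np.asarray(frames, dtype=float)
    wa = (np.ones(len(sel_a)) if weights_a is None else np.asarray(weights_a, dtype=float))
    wb = (np.ones(len(sel_b)) if weights_b is None else np.asarray(weights_b, dtype=float))
    ca = np.einsum("fij,i->fj", frames[:, sel_a, :], wa / wa.sum())
    cb = np.einsum("fij,i->fj", frames[:, sel_b, :], wb / wb.sum())
    d = ca - cb
    return np.sqrt(np.einsum("ij,ij->i", d, d))


# ---------------------------------------------------------------------------
# helical axis
# ---------------------------------------------------------------------------

def _window_axis_point(p: np.ndarray):
    """Local helix axis from 4 consecutive backbone points.

    Direction from the double difference of successive bond vectors
    (exact for an ideal helix); position from an algebraic circle fit of
    the points projected onto the plane perpendicular to the direction.
    Returns (point, direction).
    """
    d = np.diff(p, axis=0)                      # 3 bond vectors
    u = np.cross(d[0] - d[1], d[1] - d[2])
    nu = np.linalg.norm(u)
    if nu < 1e-10:
        # straight (untwisted) segment: axis along the chain direction
        u = p[-1] - p[0]
        u = u / np.linalg.norm(u)
        return p.mean(axis=0), u
    u = u / nu
    # basis of the normal plane
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, u)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    centered = p - p.mean(axis=0)
    xy = np.stack([centered @ e1, centered @ e2], axis=1)
    # Kasa circle fit: minimise |x^2 + y^2 - 2ax - 2by - c|
    A = np.column_stack([2.0 * xy, np.ones(len(xy))])
    b = np.einsum("ij,ij->i", xy, xy)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center2d = sol[:2]
    heights = centered @ u
    return p.mean(axis=0) + center2d[0] * e1 + center2d[1] * e2 + heights.mean() * u, u


def helix_axis(
    structure: MolecularStructure,
    helix_ranges: list[tuple[str, int, int]],
    atom_name: str = "P",
    window: int = 4,
) -> HelicalAxisProfile:
    """Sliding-window helical-axis trace over backbone P atoms.

    ``helix_ranges`` lists ``(chain, first_res, last_res)`` segments in
    the order they chain together (e.g. h28 -> h36 through the head);
    each window of ``window`` consecutive residues contributes one axis
    point attributed to the residue at the window's second position.
    """
    pts_all, pos_all, labels = [], [], []
    for h, (chain, lo, hi) in enumerate(helix_ranges):
        res = list(range(lo, hi + 1))
        coords = []
        positions = []
        for r in res:
            try:
                idx = structure.atom_index(chain, r, atom_name)
            except KeyError:
                continue
            coords.append(structure.coords[idx])
            positions.append(r)
        if len(coords) < window:
            raise ValueError(
                f"helix range {chain}:{lo}-{hi} has {len(coords)} {atom_name} atoms; "
                f"need >= {window}"
            )
        coords = np.array(coords)
        for w in range(len(coords) - window + 1):
            pt, _ = _window_axis_point(coords[w:w + window])
            pts_all.append(pt)
            pos_all.append(positions[w + 1])
            labels.append(f"helix{h}")
    return HelicalAxisProfile(np.array(pts_all), np.array(pos_all), labels)


def axis_displacement_profile(
    state_a: MolecularStructure,
    state_b: MolecularStructure,
    helix_ranges: list[tuple[str, int, int]],
    align_selection: np.ndarray | None = None,
    atom_name: str = "P",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position axis displacement (A) between two conformations.

    State B is superposed on state A (over ``align_selection`` atom
    indices, or over all atoms if omitted) before the axes are compared;
    returns ``(positions, displacements)``.
    """
    if len(state_a) != len(state_b):
        raise ValueError("conformations must share the atom list")
    coords_b = state_b.coords
    asel = (np.arange(len(state_a)) if align_selection is None
            else np.asarray(align_selection, dtype=int))
    R, t, _ = kabsch(coords_b[asel], state_a.coords[asel])
    state_b_aligned = state_b.with_coords(apply_transform(coords_b, R, t))
    prof_a = helix_axis(state_a, helix_ranges, atom_name)
    prof_b = helix_axis(state_b_aligned, helix_ranges, atom_name)
    if len(prof_a.points) != len(prof_b.points) or np.any(prof_a.positions != prof_b.positions):
        raise ValueError("axis coverage differs between the two states")
    disp = np.linalg.norm(prof_a.points - prof_b.points, axis=1)
    return prof_a.positions, disp


def locate_hinges(
    profile: np.ndarray,
    smooth_window: int = 5,
    polyorder: int = 2,
    prominence: float | None = None,
) -> list[int]:
    """Hinge positions: upward-curvature maxima of the smoothed profile.

    A hinge is where the displacement profile bends upward most sharply
    — the vertex of a V, the floor of each basin of a two-basin profile,
    or the knee where a body-aligned profile starts rising into the
    mobile domain (the inflection-point reading).  The profile is
    Savitzky-Golay smoothed (window 5, order 2 by default), its discrete
    second derivative taken, and peaks above a prominence threshold
    (default 10% of the curvature range) returned in position order.
    A flat profile yields an empty list.
    """
    y = np.asarray(profile, dtype=float)
    if len(y) < 5:
        raise ValueError("profile too short for hinge localization")
    rng = float(y.max() - y.min())
    if rng < 1e-12:
        return []
    w = min(smooth_window, len(y) if len(y) % 2 else len(y) - 1)
    smooth = savgol_filter(y, w, min(polyorder, w - 1))
    curv = np.gradient(np.gradient(smooth))
    if prominence is None:
        prominence = 0.10 * float(curv.max() - curv.min())
    peaks, _ = find_peaks(curv, prominence=prominence)
    return sorted(int(m) for m in peaks)


def pca_motion(
    frames: np.ndarray,
    selection: np.ndarray,
    align_selection: np.ndarray | None = None,
):
    """PCA of selected-atom coordinates over a trajectory.

    Frames are aligned to the first frame over ``align_selection``
    (defaults to the selection itself); returns
    ``(eigenvalues, modes, projections)`` with eigenvalues
    non-increasing, modes of shape (n_modes, n_sel, 3) and projections
    of shape (n_frames, n_modes).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 3:
        raise ValueError("PCA needs at least 3 frames")
    sel = np.asarray(selection, dtype=int)
    asel = sel if align_selection is None else np.asarray(align_selection, dtype=int)
    ref = frames[0]
    X = np.empty((frames.shape[0], len(sel) * 3))
    for f in range(frames.shape[0]):
        R, t, _ = kabsch(frames[f][asel], ref[asel])
        X[f] = apply_transform(frames[f][sel], R, t).ravel()
    Xc = X - X.mean(axis=0)
    # SVD of the centered data matrix == eigendecomposition of the covariance
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S ** 2 / frames.shape[0]
    modes = Vt.reshape(-1, len(sel), 3)
    projections = Xc @ Vt.T
    return eigvals, modes, projections
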