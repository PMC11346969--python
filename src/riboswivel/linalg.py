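"""Small geometric primitives shared across the package.

Everything here operates on plain ``numpy`` arrays so that the structure,
forcefield and measurement layers can share one tested implementation of
rigid-body superposition, internal-coordinate evaluation and the
swing--twist decomposition of a rotation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kabsch",
    "apply_transform",
    "angle_between",
    "bond_lengths",
    "bend_angles",
    "dihedral_angles",
    "wrap_angle",
    "rotation_about_axis",
    "swing_twist",
]


def kabsch(mobile: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None):
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best fits
    ``target``; ``R`` is a proper rotation (det = +1).

    Raises
    ------
    ValueError
        if fewer than 3 points are given or the point sets are
        rank-deficient (collinear), in which case the rotation is not
        uniquely determined.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"coordinate sets must share shape (n, 3); got {P.shape} vs {Q.shape}")
    if P.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    if weights is None:
        w = np.ones(len(P))
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    cP = w @ P
    cQ = w @ Q
    P0 = P - cP
    Q0 = Q - cQ
    H = (P0 * w[:, None]).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # two near-zero singular values => points effectively collinear
    if S[1] < 1e-10 * max(S[0], 1e-300):
        raise ValueError("degenerate (collinear) point set: rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ np.asarray(R).T + np.asarray(t)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in radians, numerically safe."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def bond_lengths(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Distances for index pairs ``idx`` of shape (m, 2)."""
    d = coords[idx[:, 0]] - coords[idx[:, 1]]
    return np.sqrt(np.einsum("ij,ij->i", d, d))


def bend_angles(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Bend angles theta(i, j, k) in radians for index triples (m, 3)."""
    u = coords[idx[:, 0]] - coords[idx[:, 1]]
    v = coords[idx[:, 2]] - coords[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.arccos(np.clip(c, -1.0, 1.0))


def dihedral_angles(coords: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Signed torsion angles phi(i, j, k, l) in (-pi, pi] for quads (m, 4)."""
    b1 = coords[idx[:, 1]] - coords[idx[:, 0]]
    b2 = coords[idx[:, 2]] - coords[idx[:, 1]]
    b3 = coords[idx[:, 3]] - coords[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2n)
    return np.arctan2(y, x)


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-pi, pi]."""
    return np.asarray(a) - 2.0 * np.pi * np.round(np.asarray(a) / (2.0 * np.pi))


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    x, y, z = a
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _quat_from_matrix(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w, x, y, z) of a proper rotation matrix."""
    from scipy.spatial.transform import Rotation

    x, y, z, w = Rotation.from_matrix(R).as_quat()
    q = np.array([w, x, y, z])
    if q[0] < 0:
        q = -q
    return q


def swing_twist(R: np.ndarray, axis: np.ndarray) -> tuple[float, float]:
    """Decompose a rotation into twist about ``axis`` and residual swing.

    The rotation is factored as ``R = R_swing @ R_twist`` where the twist
    is the component about ``axis`` and the swing is a rotation about an
    axis perpendicular to it.  Returns ``(twist_rad, swing_rad)`` with the
    twist signed (positive = right-handed about ``axis``) and the swing
    non-negative.
    """
    n = np.asarray(axis, dtype=float)
    n = n / np.linalg.norm(n)
    q = _quat_from_matrix(np.asarray(R, dtype=float))
    w, v = q[0], q[1:]
    proj = float(np.dot(v, n))
    twist = 2.0 * np.arctan2(proj, w)
    qt = np.array([w, *(proj * n)])
    norm = np.linalg.norm(qt)
    if norm < 1e-12:
        # pure 180-degree swing: no twist component
        return 0.0, np.pi
    qt /= norm
    # q_swing = q * conj(q_twist)
    wt, vt = qt[0], qt[1:]
    ws = w * wt + float(np.dot(v, vt))
    swing = 2.0 * np.arccos(np.clip(abs(ws), -1.0, 1.0))
    return float(twist), float(swing)
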