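"""Reference (numpy) evaluation of the potential and its analytic gradient.

This is the readable, term-by-term implementation used for energy
breakdowns, minimization and tests; the Langevin integrator uses a
numba-compiled kernel (:mod:`riboswivel._kernels`) that is checked
against this one.
"""

from __future__ import annotations

import numpy as np

from .forcefield import ForceField, dihedral_FD, dihedral_FD_prime
from .linalg import bond_lengths, bend_angles, dihedral_angles, wrap_angle

__all__ = ["potential_energy", "forces"]


def _check(ff: ForceField, coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (ff.n_atoms, 3):
        raise ValueError(f"coords shape {coords.shape} != ({ff.n_atoms}, 3)")
    return coords


def potential_energy(ff: ForceField, coords: np.ndarray):
    """Total reduced-unit potential and its per-term breakdown.

    Returns ``(V_total, breakdown)`` where the breakdown has keys
    ``bond``, ``angle``, ``improper``, ``planar``, ``dihedral_backbone``,
    ``dihedral_sidechain``, ``contact`` and ``noncontact``.
    """
    coords = _check(ff, coords)
    p = ff.parameters
    b = ff.bonded
    out = {}

    if len(b.bonds):
        r = bond_lengths(coords, b.bonds)
        out["bond"] = float(0.5 * p.eps_r * np.sum((r - b.bonds_r0) ** 2))
    else:
        out["bond"] = 0.0
    if len(b.angles):
        t = bend_angles(coords, b.angles)
        out["angle"] = float(0.5 * p.eps_theta * np.sum((t - b.angles_t0) ** 2))
    else:
        out["angle"] = 0.0
    for key, idx, ref, eps in (
        ("improper", b.impropers, b.impropers_x0, p.eps_chi_improper),
        ("planar", b.planars, b.planars_x0, p.eps_chi_planar),
    ):
        if len(idx):
            x = dihedral_angles(coords, idx)
            out[key] = float(0.5 * eps * np.sum(wrap_angle(x - ref) ** 2))
        else:
            out[key] = 0.0
    if len(b.dihedrals):
        phi = dihedral_angles(coords, b.dihedrals)
        fd = dihedral_FD(phi, b.dihedrals_p0)
        bb = b.dihedrals_backbone
        out["dihedral_backbone"] = float(p.eps_BB * np.sum(fd[bb]))
        out["dihedral_sidechain"] = float(p.eps_SC * np.sum(fd[~bb]))
    else:
        out["dihedral_backbone"] = 0.0
        out["dihedral_sidechain"] = 0.0

    c = ff.contacts
    if len(c):
        r = bond_lengths(coords, c.pairs)
        sr6 = (c.sigma / r) ** 6
        out["contact"] = float(np.sum(c.eps * (sr6 * sr6 - 2.0 * sr6)))
    else:
        out["contact"] = 0.0
    nc = ff.noncontact_pairs
    if len(nc):
        r = bond_lengths(coords, nc)
        out["noncontact"] = float(p.eps_NC * np.sum((p.sigma_NC / r) ** 12))
    else:
        out["noncontact"] = 0.0

    return float(sum(out.values())), out


def _angle_grad(coords, idx, dV_dtheta):
    """Accumulate -dV for bend-angle terms; returns force contribution."""
    F = np.zeros_like(coords)
    u = coords[idx[:, 0]] - coords[idx[:, 1]]
    v = coords[idx[:, 2]] - coords[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-14))
    dtheta_di = (c[:, None] * uh - vh) / (nu * s)[:, None]
    dtheta_dk = (c[:, None] * vh - uh) / (nv * s)[:, None]
    gi = dV_dtheta[:, None] * dtheta_di
    gk = dV_dtheta[:, None] * dtheta_dk
    np.add.at(F, idx[:, 0], -gi)
    np.add.at(F, idx[:, 2], -gk)
    np.add.at(F, idx[:, 1], gi + gk)
    return F


def _torsion_grad(coords, idx, dV_dphi):
    """Accumulate -dV for torsion terms (Blondel-Karplus gradients)."""
    F = np.zeros_like(coords)
    b1 = coords[idx[:, 1]] - coords[idx[:, 0]]
    b2 = coords[idx[:, 2]] - coords[idx[:, 1]]
    b3 = coords[idx[:, 3]] - coords[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    nb2 = np.linalg.norm(b2, axis=1)
    dphi_d1 = -(nb2 / np.maximum(n1sq, 1e-14))[:, None] * n1
    dphi_d4 = (nb2 / np.maximum(n2sq, 1e-14))[:, None] * n2
    f1 = np.einsum("ij,ij->i", b1, b2) / np.maximum(nb2 * nb2, 1e-14)
    f3 = np.einsum("ij,ij->i", b3, b2) / np.maximum(nb2 * nb2, 1e-14)
    dphi_d2 = -(1.0 + f1[:, None]) * dphi_d1 + f3[:, None] * dphi_d4
    dphi_d3 = f1[:, None] * dphi_d1 - (1.0 + f3[:, None]) * dphi_d4
    for col, g in zip(range(4), (dphi_d1, dphi_d2, dphi_d3, dphi_d4)):
        np.add.at(F, idx[:, col], -dV_dphi[:, None] * g)
    return F


def forces(ff: ForceField, coords: np.ndarray) -> np.ndarray:
    """Analytic forces -grad V, shape (N, 3)."""
    coords = _check(ff, coords)
    p = ff.parameters
    b = ff.bonded
    F = np.zeros_like(coords)

    if len(b.bonds):
        d = coords[b.bonds[:, 0]] - coords[b.bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        g = (p.eps_r * (r - b.bonds_r0) / r)[:, None] * d
        np.add.at(F, b.bonds[:, 0], -g)
        np.add.at(F, b.bonds[:, 1], g)
    if len(b.angles):
        t = bend_angles(coords, b.angles)
        F += _angle_grad(coords, b.angles, p.eps_theta * (t - b.angles_t0))
    for idx, ref, eps in ((b.impropers, b.impropers_x0, p.eps_chi_improper),
                          (b.planars, b.planars_x0, p.eps_chi_planar)):
        if len(idx):
            x = dihedral_angles(coords, idx)
            F += _torsion_grad(coords, idx, eps * wrap_angle(x - ref))
    if len(b.dihedrals):
        phi = dihedral_angles(coords, b.dihedrals)
        eps_d = np.where(b.dihedrals_backbone, p.eps_BB, p.eps_SC)
        F += _torsion_grad(coords, b.dihedrals, eps_d * dihedral_FD_prime(phi, b.dihedrals_p0))

    c = ff.contacts
    if len(c):
        d = coords[c.pairs[:, 0]] - coords[c.pairs[:, 1]]
        r = np.linalg.norm(d, axis=1)
        sr6 = (c.sigma / r) ** 6
        dV_dr = -12.0 * c.eps * (sr6 * sr6 - sr6) / r
        g = (dV_dr / r)[:, None] * d
        np.add.at(F, c.pairs[:, 0], -g)
        np.add.at(F, c.pairs[:, 1], g)
    nc = ff.noncontact_pairs
    if len(nc):
        d = coords[nc[:, 0]] - coords[nc[:, 1]]
        r = np.linalg.norm(d, axis=1)
        v = p.eps_NC * (p.sigma_NC / r) ** 12
        dV_dr = -12.0 * v / r
        g = (dV_dr / r)[:, None] * d
        np.add.at(F, nc[:, 0], -g)
        np.add.at(F, nc[:, 1], g)
    return F
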