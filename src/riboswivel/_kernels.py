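"""Numba-compiled force kernel and BAOAB Langevin segment integrator.

The kernel evaluates the same potential as :mod:`riboswivel.energies`
(which is the readable reference implementation the tests check it
against) but runs in explicit loops so a simulation step costs
microseconds instead of milliseconds.  Torsion terms are packed into a
single array with a per-term mode flag: 0 = harmonic (improper/planar),
1 = the cosine FD shape used for proper dihedrals.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _wrap(a):
    return a - TWO_PI * np.round(a / TWO_PI)


@njit(cache=True)
def compute_forces_kernel(
    x,
    F,
    bonds, bonds_r0, eps_r,
    angles, angles_t0, eps_theta,
    tors, tors_x0, tors_eps, tors_fd,
    con_pairs, con_sigma, con_eps,
    nc_pairs, eps_nc, sig_nc,
):
    n = x.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0

    for m in range(bonds.shape[0]):
        i = bonds[m, 0]
        j = bonds[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        g = eps_r * (r - bonds_r0[m]) / r
        F[i, 0] -= g * dx
        F[i, 1] -= g * dy
        F[i, 2] -= g * dz
        F[j, 0] += g * dx
        F[j, 1] += g * dy
        F[j, 2] += g * dz

    for m in range(angles.shape[0]):
        i = angles[m, 0]
        j = angles[m, 1]
        k = angles[m, 2]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]
        vy = x[k, 1] - x[j, 1]
        vz = x[k, 2] - x[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
        vhx, vhy, vhz = vx / nv, vy / nv, vz / nv
        c = uhx * vhx + uhy * vhy + uhz * vhz
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        s2 = 1.0 - c * c
        if s2 < 1e-14:
            s2 = 1e-14
        s = np.sqrt(s2)
        theta = np.arccos(c)
        dV = eps_theta * (theta - angles_t0[m])
        gix = dV * (c * uhx - vhx) / (nu * s)
        giy = dV * (c * uhy - vhy) / (nu * s)
        giz = dV * (c * uhz - vhz) / (nu * s)
        gkx = dV * (c * vhx - uhx) / (nv * s)
        gky = dV * (c * vhy - uhy) / (nv * s)
        gkz = dV * (c * vhz - uhz) / (nv * s)
        F[i, 0] -= gix
        F[i, 1] -= giy
        F[i, 2] -= giz
        F[k, 0] -= gkx
        F[k, 1] -= gky
        F[k, 2] -= gkz
        F[j, 0] += gix + gkx
        F[j, 1] += giy + gky
        F[j, 2] += giz + gkz

    for m in range(tors.shape[0]):
        i = tors[m, 0]
        j = tors[m, 1]
        k = tors[m, 2]
        l = tors[m, 3]
        b1x = x[j, 0] - x[i, 0]
        b1y = x[j, 1] - x[i, 1]
        b1z = x[j, 2] - x[i, 2]
        b2x = x[k, 0] - x[j, 0]
        b2y = x[k, 1] - x[j, 1]
        b2z = x[k, 2] - x[j, 2]
        b3x = x[l, 0] - x[k, 0]
        b3y = x[l, 1] - x[k, 1]
        b3z = x[l, 2] - x[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-14:
            n1sq = 1e-14
        if n2sq < 1e-14:
            n2sq = 1e-14
        b2sq = b2x * b2x + b2y * b2y + b2z * b2z
        nb2 = np.sqrt(b2sq)
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        yv = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        xv = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(yv, xv)
        d = _wrap(phi - tors_x0[m])
        if tors_fd[m] == 1:
            dV = tors_eps[m] * (np.sin(d) + 1.5 * np.sin(3.0 * d))
        else:
            dV = tors_eps[m] * d
        s1 = -nb2 / n1sq
        s4 = nb2 / n2sq
        d1x, d1y, d1z = s1 * n1x, s1 * n1y, s1 * n1z
        d4x, d4y, d4z = s4 * n2x, s4 * n2y, s4 * n2z
        f1 = (b1x * b2x + b1y * b2y + b1z * b2z) / b2sq
        f3 = (b3x * b2x + b3y * b2y + b3z * b2z) / b2sq
        d2x = -(1.0 + f1) * d1x + f3 * d4x
        d2y = -(1.0 + f1) * d1y + f3 * d4y
        d2z = -(1.0 + f1) * d1z + f3 * d4z
        d3x = f1 * d1x - (1.0 + f3) * d4x
        d3y = f1 * d1y - (1.0 + f3) * d4y
        d3z = f1 * d1z - (1.0 + f3) * d4z
        F[i, 0] -= dV * d1x
        F[i, 1] -= dV * d1y
        F[i, 2] -= dV * d1z
        F[j, 0] -= dV * d2x
        F[j, 1] -= dV * d2y
        F[j, 2] -= dV * d2z
        F[k, 0] -= dV * d3x
        F[k, 1] -= dV * d3y
        F[k, 2] -= dV * d3z
        F[l, 0] -= dV * d4x
        F[l, 1] -= dV * d4y
        F[l, 2] -= dV * d4z

    for m in range(con_pairs.shape[0]):
        i = con_pairs[m, 0]
        j = con_pairs[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        sr6 = (con_sigma[m] * con_sigma[m] / r2) ** 3
        dV_r = -12.0 * con_eps[m] * (sr6 * sr6 - sr6) / r2
        F[i, 0] -= dV_r * dx
        F[i, 1] -= dV_r * dy
        F[i, 2] -= dV_r * dz
        F[j, 0] += dV_r * dx
        F[j, 1] += dV_r * dy
        F[j, 2] += dV_r * dz

    for m in range(nc_pairs.shape[0]):
        i = nc_pairs[m, 0]
        j = nc_pairs[m, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        sr12 = (sig_nc * sig_nc / r2) ** 6
        dV_r = -12.0 * eps_nc * sr12 / r2
        F[i, 0] -= dV_r * dx
        F[i, 1] -= dV_r * dy
        F[i, 2] -= dV_r * dz
        F[j, 0] += dV_r * dx
        F[j, 1] += dV_r * dy
        F[j, 2] += dV_r * dz


@njit(cache=True)
def baoab_segment(
    x, v, F, masses, nsteps, dt, c1, noise_scale, noise,
    bonds, bonds_r0, eps_r,
    angles, angles_t0, eps_theta,
    tors, tors_x0, tors_eps, tors_fd,
    con_pairs, con_sigma, con_eps,
    nc_pairs, eps_nc, sig_nc,
):
    """Advance ``nsteps`` BAOAB steps in place; noise is pre-drawn (nsteps, N, 3).

    ``F`` must hold the forces at the entry coordinates; it holds the
    forces at the exit coordinates on return, so segments chain with one
    force evaluation per step.
    """
    n = x.shape[0]
    half = 0.5 * dt
    for step in range(nsteps):
        for i in range(n):
            inv_m = 1.0 / masses[i]
            sq = np.sqrt(inv_m)
            for d in range(3):
                v[i, d] += half * F[i, d] * inv_m
                x[i, d] += half * v[i, d]
                v[i, d] = c1 * v[i, d] + noise_scale * sq * noise[step, i, d]
                x[i, d] += half * v[i, d]
        compute_forces_kernel(x, F, bonds, bonds_r0, eps_r, angles, angles_t0,
                              eps_theta, tors, tors_x0, tors_eps, tors_fd,
                              con_pairs, con_sigma, con_eps, nc_pairs, eps_nc, sig_nc)
        for i in range(n):
            inv_m = 1.0 / masses[i]
            for d in range(3):
                v[i, d] += half * F[i, d] * inv_m
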