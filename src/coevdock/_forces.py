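"""Numba force kernels for the C-alpha structure-based model.

The bead counts here are small (tens to a few hundred particles), so the
cost of a force evaluation is dominated by interpreter overhead when done
with array operations; a compiled scalar loop is two orders of magnitude
faster and makes the seven-stage annealing protocol cheap.  The kernels
write forces in place and return a per-term energy vector in the order
(bonds, angles, dihedrals, intra_contacts, dca_contacts, excluded_volume).
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_TERMS = 6


@njit(cache=True, fastmath=False)
def force_kernel(x,
                 bi, bj, br0, bk,
                 ai, aj, ak, a0, aka,
                 di, dj, dk, dl, d0, dkd,
                 ci, cj, cr0, ca, cw,
                 gi, gj, gr0, ga, gw,
                 ri, rj,
                 sigma_ex, eps, forces):
    """Accumulate forces; return (energy_terms, min_pair_distance_sq)."""
    energies = np.zeros(N_TERMS)
    n = x.shape[0]
    for p in range(n):
        forces[p, 0] = 0.0
        forces[p, 1] = 0.0
        forces[p, 2] = 0.0
    min_r2 = 1.0e30

    # bonds: 0.5 k (r - r0)^2
    for m in range(bi.shape[0]):
        i = bi[m]
        j = bj[m]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < min_r2:
            min_r2 = r2
        r = np.sqrt(r2)
        dr = r - br0[m]
        energies[0] += 0.5 * bk[m] * dr * dr
        coef = -bk[m] * dr / r
        forces[i, 0] += coef * dx
        forces[i, 1] += coef * dy
        forces[i, 2] += coef * dz
        forces[j, 0] -= coef * dx
        forces[j, 1] -= coef * dy
        forces[j, 2] -= coef * dz

    # angles: 0.5 k (theta - theta0)^2
    for m in range(ai.shape[0]):
        i = ai[m]
        j = aj[m]
        k = ak[m]
        ux = x[i, 0] - x[j, 0]
        uy = x[i, 1] - x[j, 1]
        uz = x[i, 2] - x[j, 2]
        vx = x[k, 0] - x[j, 0]
        vy = x[k, 1] - x[j, 1]
        vz = x[k, 2] - x[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s2 = 1.0 - c * c
        if s2 < 1e-12:
            s2 = 1e-12
        sin = np.sqrt(s2)
        dth = theta - a0[m]
        energies[1] += 0.5 * aka[m] * dth * dth
        coef = aka[m] * dth / sin
        inv_uv = 1.0 / (nu * nv)
        inv_u2 = c / (nu * nu)
        inv_v2 = c / (nv * nv)
        fix = coef * (vx * inv_uv - ux * inv_u2)
        fiy = coef * (vy * inv_uv - uy * inv_u2)
        fiz = coef * (vz * inv_uv - uz * inv_u2)
        fkx = coef * (ux * inv_uv - vx * inv_v2)
        fky = coef * (uy * inv_uv - vy * inv_v2)
        fkz = coef * (uz * inv_uv - vz * inv_v2)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz

    # dihedrals: k [(1 - cos(dphi)) + 0.5 (1 - cos(3 dphi))]
    for m in range(di.shape[0]):
        p1 = di[m]
        p2 = dj[m]
        p3 = dk[m]
        p4 = dl[m]
        b1x = x[p2, 0] - x[p1, 0]
        b1y = x[p2, 1] - x[p1, 1]
        b1z = x[p2, 2] - x[p1, 2]
        b2x = x[p3, 0] - x[p2, 0]
        b2y = x[p3, 1] - x[p2, 1]
        b2z = x[p3, 2] - x[p2, 2]
        b3x = x[p4, 0] - x[p3, 0]
        b3y = x[p4, 1] - x[p3, 1]
        b3z = x[p4, 2] - x[p3, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        m1x = (n1y * b2z - n1z * b2y) / nb2
        m1y = (n1z * b2x - n1x * b2z) / nb2
        m1z = (n1x * b2y - n1y * b2x) / nb2
        xc = n1x * n2x + n1y * n2y + n1z * n2z
        yc = m1x * n2x + m1y * n2y + m1z * n2z
        phi = np.arctan2(yc, xc)
        dphi = phi - d0[m]
        energies[2] += dkd[m] * ((1.0 - np.cos(dphi))
                                 + 0.5 * (1.0 - np.cos(3.0 * dphi)))
        dvdphi = dkd[m] * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        gix = nb2 / n1sq * n1x
        giy = nb2 / n1sq * n1y
        giz = nb2 / n1sq * n1z
        glx = -nb2 / n2sq * n2x
        gly = -nb2 / n2sq * n2y
        glz = -nb2 / n2sq * n2z
        t = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        s = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        gjx = -(1.0 + t) * gix + s * glx
        gjy = -(1.0 + t) * giy + s * gly
        gjz = -(1.0 + t) * giz + s * glz
        gkx = t * gix - (1.0 + s) * glx
        gky = t * giy - (1.0 + s) * gly
        gkz = t * giz - (1.0 + s) * glz
        forces[p1, 0] -= dvdphi * gix
        forces[p1, 1] -= dvdphi * giy
        forces[p1, 2] -= dvdphi * giz
        forces[p2, 0] -= dvdphi * gjx
        forces[p2, 1] -= dvdphi * gjy
        forces[p2, 2] -= dvdphi * gjz
        forces[p3, 0] -= dvdphi * gkx
        forces[p3, 1] -= dvdphi * gky
        forces[p3, 2] -= dvdphi * gkz
        forces[p4, 0] -= dvdphi * glx
        forces[p4, 1] -= dvdphi * gly
        forces[p4, 2] -= dvdphi * glz

    # Gaussian contact wells with excluded volume, intra- then inter-chain
    for term in range(2):
        if term == 0:
            ii, jj, rr0, aa, ww = ci, cj, cr0, ca, cw
            slot = 3
        else:
            ii, jj, rr0, aa, ww = gi, gj, gr0, ga, gw
            slot = 4
        for m in range(ii.shape[0]):
            i = ii[m]
            j = jj[m]
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < min_r2:
                min_r2 = r2
            r = np.sqrt(r2)
            inv = sigma_ex / r
            inv2 = inv * inv
            inv6 = inv2 * inv2 * inv2
            rep = eps * inv6 * inv6
            gauss = aa[m] * eps * np.exp(-(r - rr0[m]) * (r - rr0[m])
                                         / (2.0 * ww[m] * ww[m]))
            energies[slot] += rep - gauss
            dvdr = -12.0 * rep / r + gauss * (r - rr0[m]) / (ww[m] * ww[m])
            coef = -dvdr / r
            forces[i, 0] += coef * dx
            forces[i, 1] += coef * dy
            forces[i, 2] += coef * dz
            forces[j, 0] -= coef * dx
            forces[j, 1] -= coef * dy
            forces[j, 2] -= coef * dz

    # plain excluded volume
    sig2 = sigma_ex * sigma_ex
    for m in range(ri.shape[0]):
        i = ri[m]
        j = rj[m]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < min_r2:
            min_r2 = r2
        inv2 = sig2 / r2
        inv6 = inv2 * inv2 * inv2
        rep = eps * inv6 * inv6
        energies[5] += rep
        coef = 12.0 * rep / r2
        forces[i, 0] += coef * dx
        forces[i, 1] += coef * dy
        forces[i, 2] += coef * dz
        forces[j, 0] -= coef * dx
        forces[j, 1] -= coef * dy
        forces[j, 2] -= coef * dz

    return energies, min_r2


@njit(cache=True)
def baoab_chunk(x, v, dt, gamma, temperature, noise,
                bi, bj, br0, bk,
                ai, aj, ak, a0, aka,
                di, dj, dk, dl, d0, dkd,
                ci, cj, cr0, ca, cw,
                gi, gj, gr0, ga, gw,
                ri, rj,
                sigma_ex, eps, forces):
    """Integrate ``noise.shape[0]`` BAOAB steps in place.

    ``forces`` must hold the forces at the entry coordinates and holds the
    forces at the exit coordinates on return.  Returns
    (status, min_pair_distance_sq): status 1 on coordinate explosion.
    """
    n_steps = noise.shape[0]
    n = x.shape[0]
    half = 0.5 * dt
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * temperature)
    min_r2 = 1.0e30
    for step in range(n_steps):
        for p in range(n):
            for u in range(3):
                v[p, u] += half * forces[p, u]
                x[p, u] += half * v[p, u]
        if gamma > 0.0:
            for p in range(n):
                for u in range(3):
                    v[p, u] = c1 * v[p, u] + c2 * noise[step, p, u]
        for p in range(n):
            for u in range(3):
                x[p, u] += half * v[p, u]
                if np.abs(x[p, u]) > 1.0e4:
                    return 1, min_r2
        _, r2 = force_kernel(x, bi, bj, br0, bk, ai, aj, ak, a0, aka,
                             di, dj, dk, dl, d0, dkd,
                             ci, cj, cr0, ca, cw, gi, gj, gr0, ga, gw,
                             ri, rj, sigma_ex, eps, forces)
        if r2 < min_r2:
            min_r2 = r2
        for p in range(n):
            for u in range(3):
                v[p, u] += half * forces[p, u]
    return 0, min_r2
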