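"""Numba kernels for the two heaviest energy terms.

These are straight scalar-loop transcriptions of the formulas in
``forcefield`` (structure-based protein stand-in; heme internal bonded +
nonbonded).  They exist purely for speed in the dynamics hot path; the
test suite checks them against independent naive implementations to
1e-10 relative, like every other term.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def standin_kernel(ca, cb, o,
                   pair_kind, pair_a, pair_b, pair_d0,
                   bka, bia, bkb, bib, bond_d0,
                   chi_mid, chi_c0,
                   eps, w2, kb, kchi,
                   g_ca, g_cb, g_o, want_grad):
    energy = 0.0
    # Gaussian wells on native pair distances
    for p in range(pair_kind.shape[0]):
        if pair_kind[p] == 0:
            pos = ca
            grad = g_ca
        else:
            pos = cb
            grad = g_cb
        a = pair_a[p]
        b = pair_b[p]
        dx = pos[a, 0] - pos[b, 0]
        dy = pos[a, 1] - pos[b, 1]
        dz = pos[a, 2] - pos[b, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - pair_d0[p]
        g = np.exp(-d * d / (2.0 * w2))
        energy -= eps * g
        if want_grad:
            c = eps * d / w2 * g / r
            grad[a, 0] += c * dx
            grad[a, 1] += c * dy
            grad[a, 2] += c * dz
            grad[b, 0] -= c * dx
            grad[b, 1] -= c * dy
            grad[b, 2] -= c * dz
    # chain-connectivity harmonic bonds (kind codes: 0 ca, 1 cb, 2 o)
    for p in range(bka.shape[0]):
        if bka[p] == 0:
            pa, ga = ca, g_ca
        elif bka[p] == 1:
            pa, ga = cb, g_cb
        else:
            pa, ga = o, g_o
        if bkb[p] == 0:
            pb, gb = ca, g_ca
        elif bkb[p] == 1:
            pb, gb = cb, g_cb
        else:
            pb, gb = o, g_o
        a = bia[p]
        b = bib[p]
        dx = pa[a, 0] - pb[b, 0]
        dy = pa[a, 1] - pb[b, 1]
        dz = pa[a, 2] - pb[b, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - bond_d0[p]
        energy += kb * d * d
        if want_grad:
            c = 2.0 * kb * d / r
            ga[a, 0] += c * dx
            ga[a, 1] += c * dy
            ga[a, 2] += c * dz
            gb[b, 0] -= c * dx
            gb[b, 1] -= c * dy
            gb[b, 2] -= c * dz
    # chirality: harmonic on the triple product
    for p in range(chi_mid.shape[0]):
        i = chi_mid[p]
        ax = ca[i, 0] - ca[i - 1, 0]
        ay = ca[i, 1] - ca[i - 1, 1]
        az = ca[i, 2] - ca[i - 1, 2]
        bx = ca[i + 1, 0] - ca[i, 0]
        by = ca[i + 1, 1] - ca[i, 1]
        bz = ca[i + 1, 2] - ca[i, 2]
        vx = cb[i, 0] - ca[i, 0]
        vy = cb[i, 1] - ca[i, 1]
        vz = cb[i, 2] - ca[i, 2]
        cxx = ay * bz - az * by
        cxy = az * bx - ax * bz
        cxz = ax * by - ay * bx
        c = cxx * vx + cxy * vy + cxz * vz
        d = c - chi_c0[p]
        energy += kchi * d * d
        if want_grad:
            w = 2.0 * kchi * d
            # dc/da = b x v ; dc/db = v x a ; dc/dv = a x b
            dax = by * vz - bz * vy
            day = bz * vx - bx * vz
            daz = bx * vy - by * vx
            dbx = vy * az - vz * ay
            dby = vz * ax - vx * az
            dbz = vx * ay - vy * ax
            g_ca[i - 1, 0] -= w * dax
            g_ca[i - 1, 1] -= w * day
            g_ca[i - 1, 2] -= w * daz
            g_ca[i, 0] += w * (dax - dbx - cxx)
            g_ca[i, 1] += w * (day - dby - cxy)
            g_ca[i, 2] += w * (daz - dbz - cxz)
            g_ca[i + 1, 0] += w * dbx
            g_ca[i + 1, 1] += w * dby
            g_ca[i + 1, 2] += w * dbz
            g_cb[i, 0] += w * cxx
            g_cb[i, 1] += w * cxy
            g_cb[i, 2] += w * cxz
    return energy


@njit(cache=False)
def heme_internal_kernel(x,
                         bi, bj, bk, br0,
                         ai, aj, ak, akf, ath0,
                         di, dj, dk, dl, dkf, dn, dgam,
                         nbi, nbj, slj, sc, sig, eps, qq,
                         kc, g, want_grad):
    energy = 0.0
    for p in range(bi.shape[0]):
        a, b = bi[p], bj[p]
        dx = x[a, 0] - x[b, 0]
        dy = x[a, 1] - x[b, 1]
        dz = x[a, 2] - x[b, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - br0[p]
        energy += bk[p] * d * d
        if want_grad:
            c = 2.0 * bk[p] * d / r
            g[a, 0] += c * dx
            g[a, 1] += c * dy
            g[a, 2] += c * dz
            g[b, 0] -= c * dx
            g[b, 1] -= c * dy
            g[b, 2] -= c * dz
    for p in range(ai.shape[0]):
        i1, i2, i3 = ai[p], aj[p], ak[p]
        ux = x[i1, 0] - x[i2, 0]
        uy = x[i1, 1] - x[i2, 1]
        uz = x[i1, 2] - x[i2, 2]
        vx = x[i3, 0] - x[i2, 0]
        vy = x[i3, 1] - x[i2, 1]
        vz = x[i3, 2] - x[i2, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        d = th - ath0[p]
        energy += akf[p] * d * d
        if want_grad:
            s = np.sqrt(max(1.0 - c * c, 1e-12))
            w = 2.0 * akf[p] * d
            uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
            vhx, vhy, vhz = vx / nv, vy / nv, vz / nv
            g1x = (c * uhx - vhx) / (nu * s)
            g1y = (c * uhy - vhy) / (nu * s)
            g1z = (c * uhz - vhz) / (nu * s)
            g3x = (c * vhx - uhx) / (nv * s)
            g3y = (c * vhy - uhy) / (nv * s)
            g3z = (c * vhz - uhz) / (nv * s)
            g[i1, 0] += w * g1x
            g[i1, 1] += w * g1y
            g[i1, 2] += w * g1z
            g[i3, 0] += w * g3x
            g[i3, 1] += w * g3y
            g[i3, 2] += w * g3z
            g[i2, 0] -= w * (g1x + g3x)
            g[i2, 1] -= w * (g1y + g3y)
            g[i2, 2] -= w * (g1z + g3z)
    for p in range(di.shape[0]):
        i1, i2, i3, i4 = di[p], dj[p], dk[p], dl[p]
        b1x = x[i2, 0] - x[i1, 0]
        b1y = x[i2, 1] - x[i1, 1]
        b1z = x[i2, 2] - x[i1, 2]
        b2x = x[i3, 0] - x[i2, 0]
        b2y = x[i3, 1] - x[i2, 1]
        b2z = x[i3, 2] - x[i2, 2]
        b3x = x[i4, 0] - x[i3, 0]
        b3y = x[i4, 1] - x[i3, 1]
        b3z = x[i4, 2] - x[i3, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        mx = n1y * n2z - n1z * n2y
        my = n1z * n2x - n1x * n2z
        mz = n1x * n2y - n1y * n2x
        yy = (mx * b2x + my * b2y + mz * b2z) / nb2
        xx = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(yy, xx)
        arg = dn[p] * phi - dgam[p]
        energy += dkf[p] * (1.0 + np.cos(arg))
        if want_grad:
            w = -dkf[p] * dn[p] * np.sin(arg)
            n1sq = max(n1x * n1x + n1y * n1y + n1z * n1z, 1e-18)
            n2sq = max(n2x * n2x + n2y * n2y + n2z * n2z, 1e-18)
            g1x = -nb2 / n1sq * n1x
            g1y = -nb2 / n1sq * n1y
            g1z = -nb2 / n1sq * n1z
            g4x = nb2 / n2sq * n2x
            g4y = nb2 / n2sq * n2y
            g4z = nb2 / n2sq * n2z
            d12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
            d32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
            g2x = -(1.0 + d12) * g1x + d32 * g4x
            g2y = -(1.0 + d12) * g1y + d32 * g4y
            g2z = -(1.0 + d12) * g1z + d32 * g4z
            g3x = d12 * g1x - (1.0 + d32) * g4x
            g3y = d12 * g1y - (1.0 + d32) * g4y
            g3z = d12 * g1z - (1.0 + d32) * g4z
            g[i1, 0] += w * g1x
            g[i1, 1] += w * g1y
            g[i1, 2] += w * g1z
            g[i2, 0] += w * g2x
            g[i2, 1] += w * g2y
            g[i2, 2] += w * g2z
            g[i3, 0] += w * g3x
            g[i3, 1] += w * g3y
            g[i3, 2] += w * g3z
            g[i4, 0] += w * g4x
            g[i4, 1] += w * g4y
            g[i4, 2] += w * g4z
    for p in range(nbi.shape[0]):
        a, b = nbi[p], nbj[p]
        dx = x[a, 0] - x[b, 0]
        dy = x[a, 1] - x[b, 1]
        dz = x[a, 2] - x[b, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        r_soft = 0.8 * sig[p]
        rr = r if r > r_soft else r_soft
        sr2 = (sig[p] / rr) ** 2
        sr6 = sr2 * sr2 * sr2
        e_lj = slj[p] * 4.0 * eps[p] * (sr6 * sr6 - sr6)
        dlj = slj[p] * 4.0 * eps[p] * (-12.0 * sr6 * sr6 + 6.0 * sr6) / rr
        if r < r_soft:
            e_lj += dlj * (r - r_soft)
        rc = r if r > 0.5 * r_soft else 0.5 * r_soft
        e_c = sc[p] * kc * qq[p] / rc
        energy += e_lj + e_c
        if want_grad:
            dedr = dlj
            if r > 0.5 * r_soft:
                dedr -= e_c / rc
            c = dedr / r
            g[a, 0] += c * dx
            g[a, 1] += c * dy
            g[a, 2] += c * dz
            g[b, 0] -= c * dx
            g[b, 1] -= c * dy
            g[b, 2] -= c * dz
    return energy
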