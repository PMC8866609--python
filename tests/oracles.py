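"""Naive, loop-based reference implementations of every energy term.

These are written directly from the term definitions (plain Python
double loops, no vectorisation, no shared code with the package
implementation) and serve as independent oracles in the tests.
"""

import math

import numpy as np

from hemefold.model_io import reconstruct_backbone


def _norm(a, b):
    return math.sqrt(sum((float(x) - float(y)) ** 2 for x, y in zip(a, b)))


def _angle(p1, p2, p3):
    u = [float(a) - float(b) for a, b in zip(p1, p2)]
    v = [float(a) - float(b) for a, b in zip(p3, p2)]
    nu = math.sqrt(sum(x * x for x in u))
    nv = math.sqrt(sum(x * x for x in v))
    c = sum(a * b for a, b in zip(u, v)) / (nu * nv)
    return math.acos(max(-1.0, min(1.0, c)))


def fe_cc(protein, heme, params, distal=None):
    fe = heme.xyz[heme.fe_index]
    n_idx = [i for i, r in enumerate(heme.roles) if r == "N_PYRROLE"]
    if distal is not None:
        normal = heme.plane_normal()
    total = 0.0
    n = protein.n_residues
    for i in range(1, n - 1):
        aa = protein.sequence[i]
        if aa == "G":
            continue
        lam = params.lambda_fe_cc[aa]
        if lam == 0.0:
            continue
        cb = protein.cb[i]
        if distal is not None:
            side = np.sign(float(np.dot(cb - fe, normal)))
            if side == distal.face:
                continue
        r = _norm(cb, fe)
        term = math.exp(params.fe_cc_exponent_sign * (r - params.r_fe_cc) ** 2)
        for j in n_idx:
            th = _angle(cb, fe, heme.xyz[j])
            term *= (1.0 + math.tanh(
                2.0 * (math.sin(th) - math.sin(params.theta_fe_cc)))) / 2.0
        total += lam * term
    return total


def elec(protein, heme, params):
    total = 0.0
    for i in range(protein.n_residues):
        qi = protein.charges[i]
        if qi == 0.0 or not protein.has_cb[i]:
            continue
        for j in range(heme.n_atoms):
            qj = heme.partial_charges[j]
            if qj == 0.0:
                continue
            r = _norm(protein.cb[i], heme.xyz[j])
            total += (params.lambda_elec * qi * qj / r
                      * math.exp(-params.k_screening * r / params.l_screening))
    return total


def hb_backbone(protein, heme, params):
    n_site, h_site, _ = reconstruct_backbone(protein, params)
    o_idx = [i for i, r in enumerate(heme.roles) if r == "O_CARBOXYL"]
    total = 0.0
    for i in range(1, protein.n_residues - 1):
        for j in o_idx:
            r = _norm(h_site[i], heme.xyz[j])
            if r >= params.truncation_cutoff:
                continue
            th = _angle(n_site[i], h_site[i], heme.xyz[j])
            total += (params.lambda_hb_backbone
                      * math.exp(-4.0 * (r - params.r_hb) ** 2)
                      * (math.tanh(4.0 * (th - params.theta_hb) - 6.0) + 1.0)
                      / 2.0)
    return total


def hb_sidechain(protein, heme, params):
    o_idx = [i for i, r in enumerate(heme.roles) if r == "O_CARBOXYL"]
    total = 0.0
    for i in range(1, protein.n_residues - 1):
        aa = protein.sequence[i]
        if aa == "G":
            continue
        lam = params.lambda_hb_sidechain[aa]
        r0 = params.r_hb_sidechain[aa]
        for j in o_idx:
            r = _norm(protein.cb[i], heme.xyz[j])
            if r >= params.truncation_cutoff:
                continue
            total += lam * math.exp(-4.0 * (r - r0) ** 2)
    return total


def burial(protein, heme, params):
    o_idx = [i for i, r in enumerate(heme.roles) if r == "O_CARBOXYL"]
    n = protein.n_residues
    total = 0.0
    for i in range(n):
        if not protein.has_cb[i]:
            continue
        for j in o_idx:
            r = _norm(protein.cb[i], heme.xyz[j])
            total += (params.lambda_burial
                      * (1.0 - math.tanh(8.0 * (r - params.r_burial)))
                      / (4.0 * n))
    return total


def excl(protein, heme, params):
    beads = []
    for i in range(protein.n_residues):
        beads.append(protein.ca[i])
        if protein.has_cb[i]:
            beads.append(protein.cb[i])
        beads.append(protein.o[i])
    total = 0.0
    for b in beads:
        for j in range(heme.n_atoms):
            r = _norm(b, heme.xyz[j])
            if r < params.r_excl:
                total += params.lambda_excl * (r - params.r_excl) ** 2
    return total


def thioester(protein, heme, params, cys_attachments):
    v_idx = [i for i, r in enumerate(heme.roles) if r == "C_VINYL"]
    total = 0.0
    for ci in cys_attachments:
        cb = protein.cb[ci - 1]
        for j in v_idx:
            r = _norm(cb, heme.xyz[j])
            if r >= params.truncation_cutoff:
                continue
            d = r - params.r_thioester
            total += (params.lambda_cs * math.exp(-4.0 * d * d)
                      * (1.0 - math.tanh(3.0 * d))
                      * (1.0 + math.tanh(32.0 * d)))
    return total


def _dihedral(p1, p2, p3, p4):
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    b3 = np.asarray(p4, float) - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(b2 / np.linalg.norm(b2), n1)
    return math.atan2(float(m @ n2), float(n1 @ n2))


def heme_internal(heme, params):
    x = heme.xyz
    total = 0.0
    for i, j, k, r0 in heme.bonds:
        total += k * (_norm(x[i], x[j]) - r0) ** 2
    for i, j, k, kf, th0 in heme.angles:
        total += kf * (_angle(x[i], x[j], x[k]) - th0) ** 2
    for i, j, k, l, kf, nper, gamma in heme.dihedrals:
        total += kf * (1.0 + math.cos(nper * _dihedral(x[i], x[j], x[k], x[l])
                                      - gamma))
    kc = params.coulomb_constant / params.dielectric
    for i in range(heme.n_atoms):
        for j in range(i + 1, heme.n_atoms):
            if (i, j) in heme.excluded_pairs:
                continue
            s_lj = params.scale14_lj if (i, j) in heme.scaled_pairs else 1.0
            s_c = params.scale14_coulomb if (i, j) in heme.scaled_pairs else 1.0
            r = _norm(x[i], x[j])
            sig = 0.5 * (heme.lj_sigma[i] + heme.lj_sigma[j])
            eps = math.sqrt(heme.lj_epsilon[i] * heme.lj_epsilon[j])
            r_soft = 0.8 * sig
            rr = max(r, r_soft)
            sr6 = (sig / rr) ** 6
            e = 4.0 * eps * (sr6 ** 2 - sr6)
            if r < r_soft:
                slope = 4.0 * eps * (-12.0 * sr6 ** 2 + 6.0 * sr6) / rr
                e += slope * (r - r_soft)
            total += s_lj * e
            total += s_c * kc * heme.partial_charges[i] \
                * heme.partial_charges[j] / max(r, 0.5 * r_soft)
    return total


def protein_standin(protein, native, params):
    n = protein.n_residues
    total = 0.0
    eps, w = params.standin_epsilon, params.standin_width
    for i in range(n):
        for j in range(i + 3, n):
            for pos, nat_pos, ok in (
                    (protein.ca, native.ca, (True, True)),
                    (protein.cb, native.cb,
                     (protein.has_cb[i], protein.has_cb[j]))):
                if not (ok[0] and ok[1]):
                    continue
                d0 = _norm(nat_pos[i], nat_pos[j])
                if d0 > params.standin_pair_cutoff:
                    continue
                r = _norm(pos[i], pos[j])
                total += -eps * math.exp(-(r - d0) ** 2 / (2.0 * w * w))
    kb = params.standin_bond_k
    for i in range(n - 1):
        total += kb * (_norm(protein.ca[i], protein.ca[i + 1])
                       - _norm(native.ca[i], native.ca[i + 1])) ** 2
        total += kb * (_norm(protein.o[i], protein.ca[i + 1])
                       - _norm(native.o[i], native.ca[i + 1])) ** 2
    for i in range(n):
        total += kb * (_norm(protein.ca[i], protein.o[i])
                       - _norm(native.ca[i], native.o[i])) ** 2
        if protein.has_cb[i]:
            total += kb * (_norm(protein.ca[i], protein.cb[i])
                           - _norm(native.ca[i], native.cb[i])) ** 2
    kchi = params.standin_chirality_k
    for i in range(1, n - 1):
        if not protein.has_cb[i]:
            continue

        def chi(p):
            a = p.ca[i] - p.ca[i - 1]
            b = p.ca[i + 1] - p.ca[i]
            v = p.cb[i] - p.ca[i]
            return float(np.dot(np.cross(a, b), v))
        total += kchi * (chi(protein) - chi(native)) ** 2
    return total


def q_w_naive(pred_ca, ref_ca):
    n = len(pred_ca)
    total = 0.0
    for i in range(n):
        for j in range(i + 3, n):
            r = _norm(pred_ca[i], pred_ca[j])
            r0 = _norm(ref_ca[i], ref_ca[j])
            sig = 0.1 * (j - i) ** 0.15
            total += math.exp(-(r - r0) ** 2 / (2.0 * sig * sig))
    return 2.0 * total / ((n - 2) * (n - 3))
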