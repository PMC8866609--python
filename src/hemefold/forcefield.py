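"""Energy terms and forces of the hybrid protein-heme Hamiltonian.

The coupling between the coarse-grained protein and the all-atom heme is
knowledge-based and has six components for heme b

    H = V_fe_cc + V_elec + V_hb_backbone + V_hb_sidechain + V_burial + V_excl

with a seventh term, the thioester tether ``V_thioester``, added for
heme c.  The heme's internal energy is a conventional bonded + nonbonded
forcefield; the protein itself is held by a structure-based single-memory
potential (Gaussian wells on native pair distances plus chain
connectivity and chirality restraints).

Every term has an analytic gradient; ``forces`` assembles the negative
gradient over the flat particle layout of :class:`SystemState`, with the
virtual backbone sites chain-ruled onto their parent beads.

Sign conventions: the Fe coordinate-covalent radial factor is the bounded
Gaussian ``exp(-(r - r0)^2)`` paired with a negative coupling constant
(an attractive well); setting ``fe_cc.exponent_sign: +1`` in the
parameter file restores a literal growing exponential for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import _cross, _vnorm, angle_grad, dihedral_grad
from .model_io import (CoarseProtein, DistalRestraint, Heme, SystemState,
                       TopologyError, reconstruct_backbone)
from .params import ParameterSet

__all__ = [
    "EnergyBreakdown", "v_fe_cc", "v_elec", "v_hb_backbone",
    "v_hb_sidechain", "v_burial", "v_excl", "v_thioester",
    "heme_internal_energy", "protein_standin_energy", "total_energy",
    "forces", "forces_and_energy", "CouplingSwitches",
]


@dataclass
class EnergyBreakdown:
    """Per-term energies (kJ/mol); ``total`` is their exact sum."""
    fe_cc: float = 0.0
    elec: float = 0.0
    hb_backbone: float = 0.0
    hb_sidechain: float = 0.0
    burial: float = 0.0
    excl: float = 0.0
    thioester: float = 0.0
    heme_internal: float = 0.0
    protein_standin: float = 0.0

    @property
    def total(self) -> float:
        return (self.fe_cc + self.elec + self.hb_backbone
                + self.hb_sidechain + self.burial + self.excl
                + self.thioester + self.heme_internal + self.protein_standin)

    def as_dict(self) -> dict[str, float]:
        d = {k: float(getattr(self, k)) for k in (
            "fe_cc", "elec", "hb_backbone", "hb_sidechain", "burial",
            "excl", "thioester", "heme_internal", "protein_standin")}
        d["total"] = self.total
        return d


@dataclass
class CouplingSwitches:
    """Per-term on/off multipliers for the protein-heme coupling.

    Used by the landscape experiments that contrast the full model with
    one in which the covalent-anchor terms are zeroed.
    """
    fe_cc: float = 1.0
    elec: float = 1.0
    hb_backbone: float = 1.0
    hb_sidechain: float = 1.0
    burial: float = 1.0
    excl: float = 1.0
    thioester: float = 1.0

    @classmethod
    def all_off(cls) -> "CouplingSwitches":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    @classmethod
    def anchors_off(cls) -> "CouplingSwitches":
        """Zero the covalent anchors (Fe coordination + thioester) only."""
        return cls(fe_cc=0.0, thioester=0.0)


def _empty_grads(protein: CoarseProtein, heme: Heme | None) -> dict:
    n = protein.n_residues
    g = {"ca": np.zeros((n, 3)), "cb": np.zeros((n, 3)),
         "o": np.zeros((n, 3))}
    if heme is not None:
        g["heme"] = np.zeros((heme.n_atoms, 3))
    return g


# ---------------------------------------------------------------------------
# Coupling terms (heme b; thioester adds heme c)
# ---------------------------------------------------------------------------

def v_fe_cc(protein: CoarseProtein, heme: Heme, params: ParameterSet,
            distal: DistalRestraint | None = None,
            grads: dict | None = None) -> float:
    """Fe coordinate-covalent restraint.

    Sum over interior, non-glycine residues of
    ``lambda_i * g(r_i) * prod_j (1 + tanh(2(sin th_ij - sin th0)))/2``
    where ``r_i = |Cbeta_i - Fe|`` and ``th_ij`` is the angle
    Cbeta_i - Fe - N_j over the four pyrrole nitrogens.  The angular
    gates select residues sitting on the ring normal.  Residues on a
    distally blocked face contribute nothing.
    """
    n_idx = heme.atoms_with_role("N_PYRROLE")
    if len(n_idx) != 4:
        raise TopologyError("heme lacks the 4 pyrrole nitrogens")
    fe_i = heme.fe_index
    fe = heme.xyz[fe_i]

    n = protein.n_residues
    lam = np.array([params.lambda_fe_cc[c] for c in protein.sequence])
    elig = np.zeros(n, dtype=bool)
    elig[1:-1] = True
    elig &= protein.has_cb
    elig &= lam != 0.0
    if distal is not None:
        normal = heme.plane_normal()
        side = np.sign((np.nan_to_num(protein.cb) - fe) @ normal)
        elig &= side != distal.face
    idx = np.flatnonzero(elig)
    if len(idx) == 0:
        return 0.0

    cb = protein.cb[idx]                       # (m, 3)
    d = cb - fe
    r = _vnorm(d)
    sign = params.fe_cc_exponent_sign
    g = np.exp(sign * (r - params.r_fe_cc) ** 2)
    s0 = np.sin(params.theta_fe_cc)

    # batched over the 4 pyrrole nitrogens: shapes (m, 4[, 3])
    npos = heme.xyz[n_idx]
    th, g_cb, g_fe, g_n = angle_grad(cb[:, None, :], fe[None, None, :], npos[None, :, :])
    u = 2.0 * (np.sin(th) - s0)
    t = np.tanh(u)
    gates = 0.5 * (1.0 + t)
    prod = gates.prod(axis=1)
    energy = float((lam[idx] * g * prod).sum())

    if grads is not None:
        uh = d / r[:, None]
        dg_dr = 2.0 * sign * (r - params.r_fe_cc) * g
        radial = (lam[idx] * dg_dr * prod)[:, None] * uh
        np.add.at(grads["cb"], idx, radial)
        grads["heme"][fe_i] -= radial.sum(axis=0)
        # gates are strictly positive (tanh argument is bounded), so the
        # leave-one-out product is safely prod / gate
        dgate = (1.0 - t * t) * np.cos(th)          # d gate / d theta
        w = ((lam[idx] * g)[:, None] * (prod[:, None] / gates) * dgate)[..., None]
        np.add.at(grads["cb"], idx, (w * g_cb).sum(axis=1))
        grads["heme"][fe_i] += (w * g_fe).sum(axis=(0, 1))
        np.add.at(grads["heme"], n_idx, (w * g_n).sum(axis=0))
    return energy


def v_elec(protein: CoarseProtein, heme: Heme, params: ParameterSet,
           grads: dict | None = None) -> float:
    """Screened electrostatics between residue charges (on Cbeta) and the
    heme partial charges: ``lambda * q_i q_j exp(-k r / l) / r``."""
    pi = np.flatnonzero(protein.has_cb & (protein.charges != 0.0))
    pj = np.flatnonzero(heme.partial_charges != 0.0)
    if len(pi) == 0 or len(pj) == 0:
        return 0.0
    cb = protein.cb[pi]
    hx = heme.xyz[pj]
    diff = cb[:, None, :] - hx[None, :, :]
    r = _vnorm(diff)
    if np.any(r < 1e-9):
        raise ValueError("coincident charge pair: electrostatic singularity")
    qq = np.outer(protein.charges[pi], heme.partial_charges[pj])
    kl = params.k_screening / params.l_screening
    screen = np.exp(-kl * r)
    e = params.lambda_elec * qq * screen / r
    energy = float(e.sum())
    if grads is not None:
        dedr = params.lambda_elec * qq * screen * (-kl / r - 1.0 / r ** 2)
        w = (dedr / r)[:, :, None] * diff
        np.add.at(grads["cb"], pi, w.sum(axis=1))
        np.add.at(grads["heme"], pj, -w.sum(axis=0))
    return energy


def _add_virtual_site_grad(grads: dict, params: ParameterSet, site: str,
                           res_idx: np.ndarray, contrib: np.ndarray) -> None:
    """Chain-rule a gradient on virtual site N/H of residues ``res_idx``
    onto the parent beads Calpha(i-1), Calpha(i) and O(i-1)."""
    c = params.virtual_sites[site]
    np.add.at(grads["ca"], res_idx - 1, c["ca_prev"] * contrib)
    np.add.at(grads["ca"], res_idx, c["ca"] * contrib)
    np.add.at(grads["o"], res_idx - 1, c["o_prev"] * contrib)


def v_hb_backbone(protein: CoarseProtein, heme: Heme, params: ParameterSet,
                  grads: dict | None = None) -> float:
    """Backbone amide H ... carboxylate O hydrogen bond.

    ``lambda * exp(-4 (r - r0)^2) * (tanh(4 (th - th0) - 6) + 1)/2`` with
    ``r = |H_i - O_j|`` and ``th`` the N_i - H_i - O_j angle.  The H and
    N sites are ideal-geometry virtual sites, so the force is pushed
    onto the neighbouring Calpha and O beads.
    """
    n = protein.n_residues
    n_site, h_site, _ = reconstruct_backbone(protein, params)
    idx = np.arange(1, n - 1)
    o_idx = heme.atoms_with_role("O_CARBOXYL")
    opos = heme.xyz[o_idx]                       # (4, 3)
    h = h_site[idx]                              # (m, 3)
    nn = n_site[idx]
    d = h[:, None, :] - opos[None, :, :]         # (m, 4, 3)
    r = _vnorm(d)
    mask = r < params.truncation_cutoff
    if not mask.any():
        return 0.0
    gauss = np.where(mask, np.exp(-4.0 * (r - params.r_hb) ** 2), 0.0)
    th, g_n, g_h, g_o = angle_grad(nn[:, None, :], h[:, None, :],
                                   opos[None, :, :])
    u = 4.0 * (th - params.theta_hb) - 6.0
    t = np.tanh(u)
    gate = 0.5 * (t + 1.0)
    e = params.lambda_hb_backbone * gauss * gate
    energy = float(e.sum())
    if grads is not None:
        uh = d / r[..., None]
        dedr = params.lambda_hb_backbone * (-8.0) * (r - params.r_hb) * gauss * gate
        dedth = np.where(mask,
                         params.lambda_hb_backbone * gauss * 2.0 * (1.0 - t * t),
                         0.0)
        gh = dedr[..., None] * uh + dedth[..., None] * g_h
        gn = dedth[..., None] * g_n
        go = -dedr[..., None] * uh + dedth[..., None] * g_o
        _add_virtual_site_grad(grads, params, "H", idx, gh.sum(axis=1))
        _add_virtual_site_grad(grads, params, "N", idx, gn.sum(axis=1))
        np.add.at(grads["heme"], o_idx, go.sum(axis=0))
    return energy


def v_hb_sidechain(protein: CoarseProtein, heme: Heme, params: ParameterSet,
                   grads: dict | None = None) -> float:
    """Sidechain Cbeta ... carboxylate O hydrogen bond with per-residue
    coupling and equilibrium distance."""
    n = protein.n_residues
    lam = np.array([params.lambda_hb_sidechain[c] for c in protein.sequence])
    r0 = np.array([params.r_hb_sidechain[c] for c in protein.sequence])
    elig = np.zeros(n, dtype=bool)
    elig[1:-1] = True
    elig &= protein.has_cb
    elig &= lam != 0.0
    idx = np.flatnonzero(elig)
    if len(idx) == 0:
        return 0.0
    o_idx = heme.atoms_with_role("O_CARBOXYL")
    cb = protein.cb[idx]
    diff = cb[:, None, :] - heme.xyz[o_idx][None, :, :]
    r = _vnorm(diff)
    mask = r < params.truncation_cutoff
    gauss = np.where(mask, np.exp(-4.0 * (r - r0[idx, None]) ** 2), 0.0)
    e = lam[idx, None] * gauss
    energy = float(e.sum())
    if grads is not None:
        dedr = np.where(mask, -8.0 * (r - r0[idx, None]) * e, 0.0)
        w = (dedr / np.maximum(r, 1e-12))[:, :, None] * diff
        np.add.at(grads["cb"], idx, w.sum(axis=1))
        np.add.at(grads["heme"], o_idx, -w.sum(axis=0))
    return energy


def v_burial(protein: CoarseProtein, heme: Heme, params: ParameterSet,
             grads: dict | None = None) -> float:
    """Desolvation penalty for burying the hydrophilic carboxylates:
    ``lambda * (1 - tanh(8 (r - r0))) / (4 N)`` summed over residues and
    carboxylate oxygens."""
    n = protein.n_residues
    idx = np.flatnonzero(protein.has_cb)
    o_idx = heme.atoms_with_role("O_CARBOXYL")
    diff = protein.cb[idx][:, None, :] - heme.xyz[o_idx][None, :, :]
    r = _vnorm(diff)
    t = np.tanh(8.0 * (r - params.r_burial))
    e = params.lambda_burial * (1.0 - t) / (4.0 * n)
    energy = float(e.sum())
    if grads is not None:
        dedr = params.lambda_burial * (-8.0) * (1.0 - t * t) / (4.0 * n)
        w = (dedr / r)[:, :, None] * diff
        np.add.at(grads["cb"], idx, w.sum(axis=1))
        np.add.at(grads["heme"], o_idx, -w.sum(axis=0))
    return energy


def v_excl(protein: CoarseProtein, heme: Heme, params: ParameterSet,
           grads: dict | None = None) -> float:
    """Excluded volume ``lambda (r - r0)^2`` for every protein bead /
    heme atom pair closer than ``r0`` (all three bead types count)."""
    n = protein.n_residues
    cb_idx = np.flatnonzero(protein.has_cb)
    beads = np.concatenate([protein.ca, protein.cb[cb_idx], protein.o])
    diff = beads[:, None, :] - heme.xyz[None, :, :]
    r = _vnorm(diff)
    viol = r < params.r_excl
    if not viol.any():
        return 0.0
    delta = np.where(viol, r - params.r_excl, 0.0)
    energy = float(params.lambda_excl * np.sum(delta ** 2))
    if grads is not None:
        dedr = 2.0 * params.lambda_excl * delta
        w = (dedr / np.maximum(r, 1e-12))[:, :, None] * diff
        per_bead = w.sum(axis=1)
        grads["ca"] += per_bead[:n]
        np.add.at(grads["cb"], cb_idx, per_bead[n:n + len(cb_idx)])
        grads["o"] += per_bead[n + len(cb_idx):]
        grads["heme"] -= w.sum(axis=0)
    return energy


def v_thioester(protein: CoarseProtein, heme: Heme, params: ParameterSet,
                cys_attachments: tuple[int, int],
                grads: dict | None = None) -> float:
    """Thioester tether between the CXXC cysteine Cbetas and the heme
    vinyl carbons (heme c only).

    ``lambda_cs * exp(-4 d^2) (1 - tanh(3 d)) (1 + tanh(32 d))`` with
    ``d = r - r0``: a narrow asymmetric well that switches on steeply
    once the pair reaches bonding distance.
    """
    if heme.heme_type != "c":
        raise TopologyError("thioester term is defined only for heme c")
    ci, cj = cys_attachments
    cys_idx = np.array([ci - 1, cj - 1], dtype=int)
    if not protein.has_cb[cys_idx].all():
        raise TopologyError("attachment cysteines must carry Cbeta")
    v_idx = heme.atoms_with_role("C_VINYL")
    cb = protein.cb[cys_idx]
    diff = cb[:, None, :] - heme.xyz[v_idx][None, :, :]
    r = _vnorm(diff)
    mask = r < params.truncation_cutoff
    d = r - params.r_thioester
    t3 = np.tanh(3.0 * d)
    t32 = np.tanh(32.0 * d)
    gauss = np.exp(-4.0 * d * d)
    e = np.where(mask, params.lambda_cs * gauss * (1.0 - t3) * (1.0 + t32), 0.0)
    energy = float(e.sum())
    if grads is not None:
        dedr = params.lambda_cs * gauss * (
            -8.0 * d * (1.0 - t3) * (1.0 + t32)
            - 3.0 * (1.0 - t3 * t3) * (1.0 + t32)
            + 32.0 * (1.0 - t32 * t32) * (1.0 - t3))
        dedr = np.where(mask, dedr, 0.0)
        w = (dedr / r)[:, :, None] * diff
        np.add.at(grads["cb"], cys_idx, w.sum(axis=1))
        np.add.at(grads["heme"], v_idx, -w.sum(axis=0))
    return energy


# ---------------------------------------------------------------------------
# Heme internal forcefield
# ---------------------------------------------------------------------------

def heme_internal_energy(heme: Heme, params: ParameterSet,
                         grads: dict | None = None) -> float:
    """Bonded (harmonic bonds/angles, periodic dihedrals) plus nonbonded
    (LJ + screened Coulomb with 1-2/1-3 exclusions, scaled 1-4) energy
    of the heme itself.  Harmonic convention: ``E = k (x - x0)^2``.

    The Lennard-Jones potential is linearized below 0.8 sigma so that
    transient overlaps at high temperature produce a bounded force.
    """
    from ._kernels import heme_internal_kernel
    x = np.ascontiguousarray(heme.xyz)
    g = grads["heme"] if grads is not None else np.zeros_like(x)
    bi, bj, bk, br0 = heme.bond_arrays
    ai, aj, ak, akf, ath0 = heme.angle_arrays
    di, dj, dk, dl, dkf, dn, dgam = heme.dihedral_arrays
    nb = heme.nb_arrays
    kc = params.coulomb_constant / params.dielectric
    return float(heme_internal_kernel(
        x, bi, bj, bk, br0, ai, aj, ak, akf, ath0,
        di, dj, dk, dl, dkf, dn, dgam,
        nb["i"], nb["j"], nb["scale_lj"], nb["scale_c"],
        nb["sigma"], nb["epsilon"], nb["qq"],
        kc, g, grads is not None))


def _heme_internal_numpy(heme: Heme, params: ParameterSet,
                         grads: dict | None = None) -> float:
    """Vectorized reference implementation of ``heme_internal_energy``
    (kept as a cross-check for the compiled kernel)."""
    x = heme.xyz
    g = grads["heme"] if grads is not None else None
    energy = 0.0

    bi, bj, bk, br0 = heme.bond_arrays
    if len(bi):
        d = x[bi] - x[bj]
        r = _vnorm(d)
        energy += float((bk * (r - br0) ** 2).sum())
        if g is not None:
            w = (2.0 * bk * (r - br0) / r)[:, None] * d
            np.add.at(g, bi, w)
            np.add.at(g, bj, -w)

    ai, aj, ak, akf, ath0 = heme.angle_arrays
    if len(ai):
        th, g1, g2, g3 = angle_grad(x[ai], x[aj], x[ak])
        energy += float((akf * (th - ath0) ** 2).sum())
        if g is not None:
            w = (2.0 * akf * (th - ath0))[:, None]
            np.add.at(g, ai, w * g1)
            np.add.at(g, aj, w * g2)
            np.add.at(g, ak, w * g3)

    di, dj, dk, dl, dkf, dn, dgam = heme.dihedral_arrays
    if len(di):
        phi, g1, g2, g3, g4 = dihedral_grad(x[di], x[dj], x[dk], x[dl])
        energy += float((dkf * (1.0 + np.cos(dn * phi - dgam))).sum())
        if g is not None:
            w = (-dkf * dn * np.sin(dn * phi - dgam))[:, None]
            np.add.at(g, di, w * g1)
            np.add.at(g, dj, w * g2)
            np.add.at(g, dk, w * g3)
            np.add.at(g, dl, w * g4)

    nb = heme.nb_arrays
    iu, ju = nb["i"], nb["j"]
    diff = x[iu] - x[ju]
    r = _vnorm(diff)
    # LJ, linearized below 0.8 sigma so thermal spikes cannot blow up
    # the integrator (constant repulsive force in the clamped region)
    r_soft = 0.8 * nb["sigma"]
    rr = np.maximum(r, r_soft)
    sr6 = (nb["sigma"] / rr) ** 6
    e_lj = nb["scale_lj"] * 4.0 * nb["epsilon"] * (sr6 ** 2 - sr6)
    dlj_drr = (nb["scale_lj"] * 4.0 * nb["epsilon"]
               * (-12.0 * sr6 ** 2 + 6.0 * sr6) / rr)
    clamped = r < r_soft
    e_lj = np.where(clamped, e_lj + dlj_drr * (r - r_soft), e_lj)
    kc = params.coulomb_constant / params.dielectric
    rc = np.maximum(r, 0.5 * r_soft)
    e_c = nb["scale_c"] * kc * nb["qq"] / rc
    energy += float(e_lj.sum() + e_c.sum())
    if g is not None:
        dedr = dlj_drr - np.where(r > 0.5 * r_soft, e_c / rc, 0.0)
        w = (dedr / r)[:, None] * diff
        np.add.at(g, iu, w)
        np.add.at(g, ju, -w)
    return float(energy)


def heme_bonded_energy(heme: Heme, params: ParameterSet) -> float:
    """Bond + angle + dihedral energy only (no nonbonded)."""
    from .geometry import angle, dihedral
    x = heme.xyz
    e = sum(k * (np.linalg.norm(x[i] - x[j]) - r0) ** 2
            for i, j, k, r0 in heme.bonds)
    e += sum(k * (float(angle(x[i], x[j], x[kk])) - th0) ** 2
             for i, j, kk, k, th0 in heme.angles)
    e += sum(k * (1.0 + np.cos(n * float(dihedral(x[i], x[j], x[kk], x[l])) - gam))
             for i, j, kk, l, k, n, gam in heme.dihedrals)
    return float(e)


# ---------------------------------------------------------------------------
# Structure-based protein stand-in
# ---------------------------------------------------------------------------

def _standin_pairs(native: CoarseProtein, params: ParameterSet):
    """Native pair list: (kind, i, j, d0) for sep >= 3 within cutoff.

    Cached on the native structure (assumed immutable once used as a
    reference)."""
    cache = getattr(native, "_standin_pair_cache", None)
    if cache is not None and cache[0] == params.standin_pair_cutoff:
        return cache[1]
    n = native.n_residues
    iu, ju = np.triu_indices(n, k=3)
    out = []
    for kind, pos, ok in (("ca", native.ca, np.ones(n, bool)),
                          ("cb", native.cb, native.has_cb)):
        keep = ok[iu] & ok[ju]
        a, b = iu[keep], ju[keep]
        d0 = np.linalg.norm(pos[a] - pos[b], axis=1)
        inside = d0 <= params.standin_pair_cutoff
        out.append((kind, a[inside], b[inside], d0[inside]))
    native._standin_pair_cache = (params.standin_pair_cutoff, out)
    return out


def _standin_flat(native: CoarseProtein, params: ParameterSet):
    """Flat index/equilibrium arrays for the stand-in kernel, cached on
    the native reference."""
    cache = getattr(native, "_standin_flat_cache", None)
    if cache is not None and cache[0] == params.standin_pair_cutoff:
        return cache[1]
    pairs = _standin_pairs(native, params)
    kind_codes = {"ca": 0, "cb": 1}
    pk, pa, pb, pd0 = [], [], [], []
    for kind, a, b, d0 in pairs:
        pk.append(np.full(len(a), kind_codes[kind], dtype=np.int64))
        pa.append(a.astype(np.int64))
        pb.append(b.astype(np.int64))
        pd0.append(d0)
    n = native.n_residues
    ar = np.arange(n - 1)
    cbi = np.flatnonzero(native.has_cb)
    groups = [(0, ar, 0, ar + 1), (0, cbi, 1, cbi),
              (0, np.arange(n), 2, np.arange(n)), (2, ar, 0, ar + 1)]
    beads = (native.ca, native.cb, native.o)
    bka, bia, bkb, bib, bd0 = [], [], [], [], []
    for ka, ia, kb_, ib in groups:
        bka.append(np.full(len(ia), ka, dtype=np.int64))
        bia.append(ia.astype(np.int64))
        bkb.append(np.full(len(ib), kb_, dtype=np.int64))
        bib.append(ib.astype(np.int64))
        bd0.append(np.linalg.norm(beads[ka][ia] - beads[kb_][ib], axis=1))
    mid = np.arange(1, n - 1)
    mid = mid[native.has_cb[mid]].astype(np.int64)
    a = native.ca[mid] - native.ca[mid - 1]
    b = native.ca[mid + 1] - native.ca[mid]
    v = native.cb[mid] - native.ca[mid]
    c0 = np.sum(_cross(a, b) * v, axis=1)
    flat = (np.concatenate(pk), np.concatenate(pa), np.concatenate(pb),
            np.concatenate(pd0), np.concatenate(bka), np.concatenate(bia),
            np.concatenate(bkb), np.concatenate(bib), np.concatenate(bd0),
            mid, c0)
    native._standin_flat_cache = (params.standin_pair_cutoff, flat)
    return flat


def protein_standin_energy(protein: CoarseProtein, native: CoarseProtein,
                           params: ParameterSet,
                           grads: dict | None = None) -> float:
    """Single-memory structure-based potential.

    Gaussian wells of depth ``epsilon`` and width ``width`` on every
    native Calpha-Calpha and Cbeta-Cbeta distance with sequence
    separation >= 3 (native distance within ``pair_cutoff``), harmonic
    chain-connectivity bonds (Ca-Ca, Ca-Cb, Ca-O, O-Ca'), and a
    harmonic restraint on the signed Calpha/Cbeta triple product that
    fixes local chirality.  The native structure is the global minimum
    by construction.
    """
    from ._kernels import standin_kernel
    if protein.n_residues != native.n_residues:
        raise ValueError("protein/native length mismatch")
    (pk, pa, pb, pd0, bka, bia, bkb, bib, bd0,
     chi_mid, chi_c0) = _standin_flat(native, params)
    if grads is not None:
        g_ca, g_cb, g_o = grads["ca"], grads["cb"], grads["o"]
    else:
        g_ca = g_cb = g_o = np.zeros((1, 3))
    return float(standin_kernel(
        protein.ca, protein.cb, protein.o,
        pk, pa, pb, pd0, bka, bia, bkb, bib, bd0, chi_mid, chi_c0,
        params.standin_epsilon, params.standin_width ** 2,
        params.standin_bond_k, params.standin_chirality_k,
        g_ca, g_cb, g_o, grads is not None))


def _protein_standin_numpy(protein: CoarseProtein, native: CoarseProtein,
                           params: ParameterSet,
                           grads: dict | None = None) -> float:
    """Vectorized reference implementation of ``protein_standin_energy``
    (kept as a cross-check for the compiled kernel).

    Gaussian wells of depth ``epsilon`` and width ``width`` on every
    native Calpha-Calpha and Cbeta-Cbeta distance with sequence
    separation >= 3 (native distance within ``pair_cutoff``), harmonic
    chain-connectivity bonds (Ca-Ca, Ca-Cb, Ca-O, O-Ca'), and a
    harmonic restraint on the signed Calpha/Cbeta triple product that
    fixes local chirality.  The native structure is the global minimum
    by construction.
    """
    if protein.n_residues != native.n_residues:
        raise ValueError("protein/native length mismatch")
    eps = params.standin_epsilon
    w2 = params.standin_width ** 2
    energy = 0.0
    for kind, a, b, d0 in _standin_pairs(native, params):
        pos = getattr(protein, kind)
        diff = pos[a] - pos[b]
        r = _vnorm(diff)
        gauss = np.exp(-(r - d0) ** 2 / (2.0 * w2))
        energy += float((-eps * gauss).sum())
        if grads is not None:
            dedr = eps * (r - d0) / w2 * gauss
            vec = (dedr / r)[:, None] * diff
            np.add.at(grads[kind], a, vec)
            np.add.at(grads[kind], b, -vec)

    kb = params.standin_bond_k
    bonds = []
    n = protein.n_residues
    ar = np.arange(n - 1)
    bonds.append(("ca", ar, "ca", ar + 1))
    cbi = np.flatnonzero(protein.has_cb)
    bonds.append(("ca", cbi, "cb", cbi))
    bonds.append(("ca", np.arange(n), "o", np.arange(n)))
    bonds.append(("o", ar, "ca", ar + 1))
    for ka, ia, kc, ic in bonds:
        pa, pb = getattr(protein, ka)[ia], getattr(protein, kc)[ic]
        na_, nb_ = getattr(native, ka)[ia], getattr(native, kc)[ic]
        d0 = np.linalg.norm(na_ - nb_, axis=1)
        diff = pa - pb
        r = _vnorm(diff)
        energy += float((kb * (r - d0) ** 2).sum())
        if grads is not None:
            vec = (2.0 * kb * (r - d0) / r)[:, None] * diff
            np.add.at(grads[ka], ia, vec)
            np.add.at(grads[kc], ic, -vec)

    kchi = params.standin_chirality_k
    mid = np.arange(1, n - 1)
    mid = mid[protein.has_cb[mid]]
    if len(mid) and kchi != 0.0:
        def triple(p: CoarseProtein):
            a = p.ca[mid] - p.ca[mid - 1]
            b = p.ca[mid + 1] - p.ca[mid]
            v = p.cb[mid] - p.ca[mid]
            return a, b, v, np.sum(_cross(a, b) * v, axis=1)
        a, b, v, c = triple(protein)
        _, _, _, c0 = triple(native)
        energy += float((kchi * (c - c0) ** 2).sum())
        if grads is not None:
            dedc = 2.0 * kchi * (c - c0)
            dca = _cross(b, v) * dedc[:, None]   # dc/da
            dcb = _cross(v, a) * dedc[:, None]   # dc/db
            dcv = _cross(a, b) * dedc[:, None]   # dc/dv
            np.add.at(grads["ca"], mid - 1, -dca)
            np.add.at(grads["ca"], mid, dca - dcb - dcv)
            np.add.at(grads["ca"], mid + 1, dcb)
            np.add.at(grads["cb"], mid, dcv)
    return energy


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def total_energy(state: SystemState, native: SystemState | None,
                 params: ParameterSet,
                 switches: CouplingSwitches | None = None,
                 grads: dict | None = None) -> EnergyBreakdown:
    """Full energy breakdown of the coupled system.

    The thioester term is evaluated only for heme c; asking for it on
    heme b is a hard error at the term level, and it is simply absent
    here.  ``native`` supplies the reference for the structure-based
    protein potential (pass None to score a protein-free-energy-less
    configuration, e.g. parameter sanity checks).
    """
    sw = switches or CouplingSwitches()
    bd = EnergyBreakdown()
    protein, heme = state.protein, state.heme
    if native is not None:
        bd.protein_standin = protein_standin_energy(
            protein, native.protein, params, grads=grads)
    if heme is not None:
        if sw.fe_cc != 0.0:
            bd.fe_cc = sw.fe_cc * _scaled(
                v_fe_cc, sw.fe_cc, protein, heme, params,
                distal=state.distal_restraint, grads=grads)
        if sw.elec != 0.0:
            bd.elec = sw.elec * _scaled(v_elec, sw.elec, protein, heme,
                                        params, grads=grads)
        if sw.hb_backbone != 0.0:
            bd.hb_backbone = sw.hb_backbone * _scaled(
                v_hb_backbone, sw.hb_backbone, protein, heme, params,
                grads=grads)
        if sw.hb_sidechain != 0.0:
            bd.hb_sidechain = sw.hb_sidechain * _scaled(
                v_hb_sidechain, sw.hb_sidechain, protein, heme, params,
                grads=grads)
        if sw.burial != 0.0:
            bd.burial = sw.burial * _scaled(v_burial, sw.burial, protein,
                                            heme, params, grads=grads)
        if sw.excl != 0.0:
            bd.excl = sw.excl * _scaled(v_excl, sw.excl, protein, heme,
                                        params, grads=grads)
        if heme.heme_type == "c" and sw.thioester != 0.0:
            bd.thioester = sw.thioester * _scaled(
                v_thioester, sw.thioester, protein, heme, params,
                state.cys_attachments, grads=grads)
        bd.heme_internal = heme_internal_energy(heme, params, grads=grads)
    return bd


class _ScaledGrads(dict):
    pass


def _scaled(fn, scale, *args, grads=None, **kw):
    """Evaluate a term whose gradient must be scaled by ``scale``."""
    if grads is None or scale == 1.0:
        return fn(*args, grads=grads, **kw)
    tmp = {k: np.zeros_like(v) for k, v in grads.items()}
    e = fn(*args, grads=tmp, **kw)
    for k in grads:
        grads[k] += scale * tmp[k]
    return e


def forces_and_energy(state: SystemState, native: SystemState | None,
                      params: ParameterSet,
                      switches: CouplingSwitches | None = None):
    """Analytic forces (flat particle layout of ``state``) plus the
    energy breakdown, in one pass."""
    grads = _empty_grads(state.protein, state.heme)
    bd = total_energy(state, native, params, switches=switches, grads=grads)
    cb_idx = np.flatnonzero(state.protein.has_cb)
    parts = [grads["ca"], grads["cb"][cb_idx], grads["o"]]
    if state.heme is not None:
        parts.append(grads["heme"])
    return -np.concatenate(parts, axis=0), bd


def forces(state: SystemState, native: SystemState | None,
           params: ParameterSet,
           switches: CouplingSwitches | None = None) -> np.ndarray:
    """Negative gradient of the total energy w.r.t. all mobile
    coordinates, ordered like ``SystemState.get_coords()``."""
    return forces_and_energy(state, native, params, switches=switches)[0]
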