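"""Self-contained toy systems.

Nothing in the test or analysis workflow requires external structures:
this module builds an idealized planar heme, a designable helical-hairpin
mini-protein with a genuine heme pocket (axial histidine at the Fe
coordination geometry, and for heme c a CXXC clamp at the thioester
geometry), and a scalar double-well Metropolis sampler with an exactly
known free energy for validating the histogram-reweighting machinery.

Pocket geometry is parameter-aware: the fixture is built AT the
equilibrium distances of the loaded parameter set, so energy-minimum
checks stay valid when parameters change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import CoarseProtein, Heme, SystemState, TopologyError
from .params import ParameterSet, load_parameters

__all__ = ["ToySpec", "make_ideal_heme", "make_mini_globin",
           "make_double_well_sampler", "DoubleWellSampler",
           "ConstructionError"]

CA_CB_LENGTH = 0.153  # nm
CA_CA_BOND = 0.38     # nm

#: 30-residue helical hairpin: helix (1-13), glycine-rich loop (14-17),
#: helix (18-30).  The heme b variant carries one axial His; the heme c
#: variant adds the CXXC attachment motif directly before it.
#: Pocket chemistry follows the natural families: the heme b pocket is
#: predominantly hydrophobic with the proximal His (as in globins),
#: while the heme c pocket's second helix is lined with basic/polar
#: residues that coordinate the propionates (as lysines do in
#: cytochromes).
SEQUENCE_B = "AELKALAAHLAKA" "GGSG" "ELAKLAALAELAA"
SEQUENCE_C = "AELKACAACHAKA" "GGSG" "AKQALKNLARAEA"


class ConstructionError(ValueError):
    """The requested toy geometry cannot satisfy its pocket contract."""


@dataclass
class ToySpec:
    n_residues: int = 30
    sequence: str | None = None
    heme_type: str = "b"
    axial_residue: int | None = None   # 1-based; auto: the His
    seed: int = 0


def _rotation_from_z(u: np.ndarray) -> np.ndarray:
    """Rotation matrix taking the z axis onto unit vector u."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, u)
    s = np.linalg.norm(v)
    c = float(z @ u)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def _rot2(alpha: float) -> np.ndarray:
    c, s = np.cos(alpha), np.sin(alpha)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_ideal_heme(heme_type: str = "b",
                    params: ParameterSet | None = None) -> Heme:
    """Idealized planar porphyrin (z = 0 plane, Fe at the origin).

    Four pyrrole nitrogens sit in a 0.20 nm square around the iron; the
    ring is closed through alpha and meso carbons; two propionate arms
    each end in two carboxylate oxygens and two vinyl carbons mark the
    thioester attachment points.
    """
    if params is None:
        params = load_parameters()
    names: list[str] = []
    xyz: list[np.ndarray] = []

    def add(name: str, r: float, deg: float) -> np.ndarray:
        a = np.deg2rad(deg)
        p = np.array([r * np.cos(a), r * np.sin(a), 0.0])
        names.append(name)
        xyz.append(p)
        return p

    add("FE", 0.0, 0.0)
    for name, deg in (("NA", 0), ("NB", 90), ("NC", 180), ("ND", 270)):
        add(name, 0.20, deg)
    for ring, deg in (("A", 0), ("B", 90), ("C", 180), ("D", 270)):
        add(f"C1{ring}", 0.31, deg + 24)
        add(f"C4{ring}", 0.31, deg - 24)
    for name, deg in (("CHA", 45), ("CHB", 135), ("CHC", 225), ("CHD", 315)):
        add(name, 0.33, deg)
    add("CAB", 0.46, 114)
    add("CAC", 0.46, 204)
    for arm, deg in (("A", -24), ("D", 246)):
        d = np.array([np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg)), 0.0])
        names.append(f"CA{arm}")
        xyz.append(0.45 * d)
        cg = 0.59 * d
        names.append(f"CG{arm}")
        xyz.append(cg)
        for tag, split in (("O1", 62.0), ("O2", -62.0)):
            names.append(f"{tag}{arm}")
            xyz.append(cg + 0.125 * (_rot2(np.deg2rad(split)) @ d))
    return Heme(names, np.array(xyz), heme_type, params)


# ---------------------------------------------------------------------------
# Mini-globin
# ---------------------------------------------------------------------------

def _helix_positions(n: int, phase: float, x0: float, z0: float,
                     direction: float):
    """Ideal CG alpha-helix: radius 0.23 nm, rise 0.15 nm, 100 deg/res."""
    idx = np.arange(n)
    ang = phase + direction * np.deg2rad(100.0) * idx
    ca = np.stack([x0 + 0.23 * np.cos(ang), 0.23 * np.sin(ang),
                   z0 + direction * 0.15 * idx], axis=1)
    radial = np.stack([np.cos(ang), np.sin(ang), np.zeros(n)], axis=1)
    return ca, radial


def _place_o(ca: np.ndarray) -> np.ndarray:
    """Carbonyl O beads between successive Calphas, offset off-axis."""
    n = len(ca)
    o = np.empty_like(ca)
    for i in range(n - 1):
        step = ca[i + 1] - ca[i]
        perp = np.cross(step, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(step, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        o[i] = 0.5 * (ca[i] + ca[i + 1]) + 0.12 * perp
    o[n - 1] = ca[n - 1] + 0.6 * (ca[n - 1] - ca[n - 2])
    return o


def _native_protein(sequence: str, axial: int) -> CoarseProtein:
    """Helical hairpin with the axial residue's sidechain facing -x."""
    n = len(sequence)
    n1, nloop = 13, 4
    n2 = n - n1 - nloop
    # phase chosen so the axial residue's radial direction is +x,
    # pointing into the groove between the two helices: the heme docks
    # there and its pocket spans both helices, so full engagement
    # requires the tertiary fold
    phase1 = -np.deg2rad(100.0) * (axial - 1)
    ca1, rad1 = _helix_positions(n1, phase1, 0.0, 0.0, +1.0)
    ca2, rad2 = _helix_positions(n2, 0.3, 1.45, float(ca1[-1, 2]), -1.0)
    # loop: linear interpolation between helix ends, bowed outward in y
    start, end = ca1[-1], ca2[0]
    ts = np.linspace(0.0, 1.0, nloop + 2)[1:-1]
    loop = start + ts[:, None] * (end - start)
    loop[:, 1] += 0.45 * np.sin(np.pi * ts)
    loop_rad = np.tile([0.0, 1.0, 0.0], (nloop, 1))
    ca = np.concatenate([ca1, loop, ca2], axis=0)
    radial = np.concatenate([rad1, loop_rad, rad2], axis=0)
    cb = ca + CA_CB_LENGTH * radial
    return CoarseProtein(sequence, ca, cb, _place_o(ca))


def _dock_heme(protein: CoarseProtein, heme_type: str, axial: int,
               params: ParameterSet) -> Heme:
    """Place the ideal heme against the hairpin surface.

    The axial residue's Cbeta is kept at the Fe coordination optimum on
    the ring normal (the normal itself may tilt off the pure radial
    direction); the ring is then spun/tilted to maximise clash-free
    pocket contacts and, for heme c, to bring the vinyl carbons to the
    thioester distance from the CXXC cysteine Cbetas.  Axial and
    cysteine sidechain directions are adjusted to point at their
    binding partners (sidechain rotamers are free in this
    representation).
    """
    template = make_ideal_heme(heme_type, params)
    vin = template.atoms_with_role("C_VINYL")
    p = axial - 1
    radial = protein.cb[p] - protein.ca[p]
    radial = radial / np.linalg.norm(radial)
    t1 = np.cross([0.0, 0.0, 1.0], radial)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(radial, t1)
    seq = protein.sequence
    cys = [i for i in range(len(seq)) if seq[i] == "C"] if heme_type == "c" else []
    target = CA_CB_LENGTH + params.r_thioester
    has_cb = protein.has_cb

    def evaluate(ty: float, tz: float, spin: float):
        u = radial + ty * t1 + tz * t2
        u = u / np.linalg.norm(u)
        cb_ax = protein.ca[p] + CA_CB_LENGTH * u
        fe = cb_ax + params.r_fe_cc * u
        xyz = (_rotation_from_z(u) @ _rot2(spin) @ template.xyz.T).T + fe
        cb_new = protein.cb.copy()
        cb_new[p] = cb_ax
        err = 0.0
        pairing = []
        if cys:
            options = [list(zip(vin, cys)), list(zip(vin, reversed(cys)))]
            errs = [sum((np.linalg.norm(xyz[v] - protein.ca[c]) - target) ** 2
                        for v, c in opt) for opt in options]
            pairing = options[int(np.argmin(errs))]
            err = min(errs)
            for v, c in pairing:
                d = xyz[v] - protein.ca[c]
                cb_new[c] = protein.ca[c] + CA_CB_LENGTH * d / np.linalg.norm(d)
        beads = np.concatenate([protein.ca, cb_new[has_cb], protein.o])
        dmat = np.linalg.norm(beads[:, None, :] - xyz[None, :, :], axis=2)
        clash_free = bool(dmat.min() >= params.r_excl)
        dcb = np.linalg.norm(cb_new[has_cb][:, None, :]
                             - xyz[None, :, :], axis=2).min(axis=1)
        contacts = int((dcb < params.qc_cutoff).sum())
        if heme_type == "b":
            key = (clash_free, contacts)
        else:
            key = (clash_free, contacts >= 4, -err)
        return key, (xyz, cb_new)

    tilts = np.linspace(-1.0, 1.0, 9)
    best_key, best_cfg, best_pt = None, None, None
    for ty in tilts:
        for tz in tilts:
            for spin in np.linspace(0.0, 2.0 * np.pi, 49):
                key, cfg = evaluate(ty, tz, spin)
                if best_key is None or key > best_key:
                    best_key, best_cfg, best_pt = key, cfg, (ty, tz, spin)
    # refine around the winner
    ty0, tz0, s0 = best_pt
    for ty in np.linspace(ty0 - 0.15, ty0 + 0.15, 5):
        for tz in np.linspace(tz0 - 0.15, tz0 + 0.15, 5):
            for spin in np.linspace(s0 - 0.2, s0 + 0.2, 9):
                key, cfg = evaluate(ty, tz, spin)
                if key > best_key:
                    best_key, best_cfg = key, cfg
    xyz, cb_new = best_cfg
    protein.cb[:] = cb_new
    return Heme(template.names, xyz, heme_type, params)


def _rebuild_sidechain_and_o(sequence: str, ca: np.ndarray,
                             native: CoarseProtein) -> CoarseProtein:
    """Attach Cbeta and O beads to a Calpha trace, preserving the native
    bond lengths (|Ca-Cb|, |Ca-O|, |O-Ca'|) so chain-connectivity terms
    carry no strain."""
    n = len(sequence)
    o = np.empty_like(ca)
    for i in range(n - 1):
        d1 = float(np.linalg.norm(native.o[i] - native.ca[i]))
        d2 = float(np.linalg.norm(native.o[i] - native.ca[i + 1]))
        step = ca[i + 1] - ca[i]
        ell = float(np.linalg.norm(step))
        along = np.clip((d1 ** 2 - d2 ** 2 + ell ** 2) / (2.0 * ell),
                        0.0, min(d1, ell))
        radial = np.sqrt(max(d1 ** 2 - along ** 2, 0.0))
        axis = step / ell
        perp = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(axis, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        o[i] = ca[i] + along * axis + radial * perp
    d_last = float(np.linalg.norm(native.o[n - 1] - native.ca[n - 1]))
    tail = ca[n - 1] - ca[n - 2]
    o[n - 1] = ca[n - 1] + d_last * tail / np.linalg.norm(tail)
    cb = np.zeros_like(ca)
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        axis = ca[hi] - ca[lo]
        perp = np.cross(axis, [0.0, 1.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(axis, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        if sequence[i] != "G":
            d = float(np.linalg.norm(native.cb[i] - native.ca[i]))
            cb[i] = ca[i] + d * perp
    return CoarseProtein(sequence, ca, cb, o)


def _random_coil(native: CoarseProtein,
                 rng: np.random.Generator) -> CoarseProtein:
    """Self-avoiding random walk reusing the native bond geometry."""
    sequence = native.sequence
    n = len(sequence)
    bonds = np.linalg.norm(np.diff(native.ca, axis=0), axis=1)
    for _attempt in range(200):
        ca = np.zeros((n, 3))
        ca[1] = [bonds[0], 0.0, 0.0]
        ok = True
        for i in range(2, n):
            placed = False
            for _try in range(60):
                theta = np.deg2rad(rng.uniform(85.0, 145.0))
                phi = rng.uniform(0.0, 2.0 * np.pi)
                prev = ca[i - 1] - ca[i - 2]
                prev /= np.linalg.norm(prev)
                perp = np.cross(prev, [0.0, 0.0, 1.0])
                if np.linalg.norm(perp) < 1e-8:
                    perp = np.cross(prev, [0.0, 1.0, 0.0])
                perp /= np.linalg.norm(perp)
                perp2 = np.cross(prev, perp)
                direction = (np.cos(np.pi - theta) * prev
                             + np.sin(np.pi - theta)
                             * (np.cos(phi) * perp + np.sin(phi) * perp2))
                cand = ca[i - 1] + bonds[i - 1] * direction
                if i > 2 and np.min(np.linalg.norm(
                        ca[:i - 1] - cand, axis=1)) < 0.42:
                    continue
                ca[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise ConstructionError("could not grow a self-avoiding coil")
    return _rebuild_sidechain_and_o(sequence, ca, native)


def make_mini_globin(spec: ToySpec | None = None,
                     params: ParameterSet | None = None
                     ) -> tuple[SystemState, SystemState]:
    """Build ``(native, extended)`` toy states.

    The native state is a compact helical hairpin with the heme docked
    in a real pocket: the axial His Cbeta at the Fe coordination
    optimum on the ring normal, at least 4 residues in contact under
    the Q_c cutoff, no steric clashes, and (heme c) the vinyl carbons
    tethered to the CXXC cysteines.  The extended state is the same
    sequence as a self-avoiding coil with the heme >= 3 nm away.
    """
    spec = spec or ToySpec()
    if params is None:
        params = load_parameters()
    sequence = spec.sequence
    if sequence is None:
        sequence = SEQUENCE_C if spec.heme_type == "c" else SEQUENCE_B
    if len(sequence) != spec.n_residues and spec.sequence is None:
        spec.n_residues = len(sequence)
    axial = spec.axial_residue
    if axial is None:
        if "H" not in sequence:
            raise ConstructionError("sequence has no His for the axial site")
        axial = sequence.index("H") + 1
    if not (2 <= axial <= len(sequence) - 1):
        raise ConstructionError("axial residue must be interior")

    native_protein = _native_protein(sequence, axial)
    heme = _dock_heme(native_protein, spec.heme_type, axial, params)
    native = SystemState(native_protein, heme)

    # contract checks
    from .forcefield import v_excl
    from .metrics import contact_residues
    clash = v_excl(native_protein, heme, params)
    if clash > 1e-9:
        raise ConstructionError(f"native toy has steric clashes (v_excl={clash:.3g})")
    contacts = contact_residues(native, params.qc_cutoff)
    if len(contacts) < 4:
        raise ConstructionError(
            f"native pocket has only {len(contacts)} contacts, need >= 4")

    rng = np.random.default_rng(spec.seed)
    coil = _random_coil(native_protein, rng)
    template = make_ideal_heme(spec.heme_type, params)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    from .geometry import random_rotation
    far_xyz = (random_rotation(rng) @ template.xyz.T).T \
        + coil.ca.mean(axis=0) + 3.05 * direction
    far_heme = Heme(template.names, far_xyz, spec.heme_type, params)
    extended = SystemState(coil, far_heme)
    return native, extended


# ---------------------------------------------------------------------------
# Double-well sampler (reweighting test harness)
# ---------------------------------------------------------------------------

class DoubleWellSampler:
    """Metropolis sampler on ``U(q) = a (q^2 - b)^2`` (energies in kT).

    The generating potential is known exactly, so free-energy estimates
    reconstructed from (biased) samples can be compared against analytic
    truth.  Wells sit at ``q = +-sqrt(b)``; the barrier height is
    ``a b^2``.
    """

    def __init__(self, seed: int, a: float = 64.0, b: float = 0.25,
                 step: float = 0.15):
        self.a = float(a)
        self.b = float(b)
        self.step = float(step)
        self.rng = np.random.default_rng(seed)

    def potential(self, q):
        q = np.asarray(q, dtype=float)
        return self.a * (q * q - self.b) ** 2

    def sample(self, n_steps: int, q_init: float = 0.5, kT: float = 1.0,
               bias_k: float = 0.0, bias_q0: float = 0.0):
        """Run Metropolis; returns ``(samples, acceptance_rate)``.

        An optional harmonic bias ``0.5 k (q - q0)^2`` is added to the
        potential (umbrella window emulation).
        """
        def u(q):
            return (self.potential(q)
                    + 0.5 * bias_k * (q - bias_q0) ** 2) / kT
        q = float(q_init)
        uq = u(q)
        out = np.empty(n_steps)
        accepted = 0
        jumps = self.rng.normal(0.0, self.step, size=n_steps)
        unif = self.rng.random(n_steps)
        for t in range(n_steps):
            cand = q + jumps[t]
            uc = u(cand)
            if uc <= uq or unif[t] < np.exp(uq - uc):
                q, uq = cand, uc
                accepted += 1
            out[t] = q
        return out, accepted / n_steps


def make_double_well_sampler(seed: int, **kwargs) -> DoubleWellSampler:
    """Factory kept for a uniform fixture-building API."""
    return DoubleWellSampler(seed, **kwargs)
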