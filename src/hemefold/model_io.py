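"""Structures and PDB I/O.

The protein is coarse-grained to three beads per residue — Calpha, Cbeta
and carbonyl O (glycine has no Cbeta) — while the heme cofactor keeps all
its heavy atoms.  Remaining backbone sites (amide N, amide H, carbonyl C)
are reconstructed on the fly as fixed affine combinations of neighbouring
bead coordinates, assuming ideal peptide geometry.

Internal units are nm; PDB files are read and written in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .params import ParameterSet, load_parameters

__all__ = [
    "ResidueBead", "CoarseProtein", "HemeAtom", "Heme", "DistalRestraint",
    "SystemState", "PDBParseError", "TopologyError",
    "read_pdb", "write_pdb", "coarse_grain", "reconstruct_backbone",
]

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Unit charges placed on Cbeta: acidic -1, basic +1, everything else
#: (including histidine, taken neutral at physiological pH) 0.
RESIDUE_CHARGE = {"D": -1, "E": -1, "K": 1, "R": 1}

# Sidechain masses (amu); backbone mass is split as 56 on Calpha, 16 on O.
_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 81.0, "I": 57.0, "K": 72.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 41.0, "Q": 72.0, "R": 100.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}
_ELEMENT_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "FE": 55.845,
                 "S": 32.06, "H": 1.008}

#: Default role map for PDB v3 HEM/HEC atom naming.
DEFAULT_ROLE_MAP = {
    "FE": "FE",
    "NA": "N_PYRROLE", "NB": "N_PYRROLE", "NC": "N_PYRROLE", "ND": "N_PYRROLE",
    "O1A": "O_CARBOXYL", "O2A": "O_CARBOXYL",
    "O1D": "O_CARBOXYL", "O2D": "O_CARBOXYL",
    "CAB": "C_VINYL", "CAC": "C_VINYL",
}

# Bonded skeleton of the idealized porphyrin, by atom name.  Atoms present
# in a structure but absent from this template are attached to their
# nearest neighbour.
HEME_BOND_TEMPLATE = [
    ("FE", "NA"), ("FE", "NB"), ("FE", "NC"), ("FE", "ND"),
    ("NA", "C1A"), ("NA", "C4A"), ("NB", "C1B"), ("NB", "C4B"),
    ("NC", "C1C"), ("NC", "C4C"), ("ND", "C1D"), ("ND", "C4D"),
    ("C1A", "CHA"), ("CHA", "C4B"), ("C1B", "CHB"), ("CHB", "C4C"),
    ("C1C", "CHC"), ("CHC", "C4D"), ("C1D", "CHD"), ("CHD", "C4A"),
    ("C1B", "CAB"), ("C1C", "CAC"),
    ("C4A", "CAA"), ("CAA", "CGA"), ("CGA", "O1A"), ("CGA", "O2A"),
    ("C4D", "CAD"), ("CAD", "CGD"), ("CGD", "O1D"), ("CGD", "O2D"),
]


class PDBParseError(ValueError):
    """Malformed PDB content."""


class TopologyError(ValueError):
    """Structure violates the model's topology requirements."""


@dataclass
class ResidueBead:
    """One coarse-grained residue: Calpha, Cbeta, carbonyl O (nm)."""
    index: int                      # 1-based ordinal
    aa: str                         # one-letter code
    ca: np.ndarray
    cb: np.ndarray | None           # None for glycine
    o: np.ndarray
    charge: int
    is_terminal: bool = False

    @property
    def is_glycine(self) -> bool:
        return self.aa == "G"

    @property
    def is_cysteine(self) -> bool:
        return self.aa == "C"


class CoarseProtein:
    """Ordered chain of residue beads, stored as coordinate arrays.

    ``cb`` rows of glycine residues hold NaN and are excluded from every
    sidechain sum via :attr:`has_cb`.
    """

    def __init__(self, sequence: str, ca: np.ndarray, cb: np.ndarray,
                 o: np.ndarray):
        sequence = str(sequence).upper()
        n = len(sequence)
        if n < 4:
            raise TopologyError(f"need at least 4 residues, got {n}")
        bad = [c for c in sequence if c not in ONE_TO_THREE]
        if bad:
            raise TopologyError(f"unknown residue codes {bad!r}")
        self.sequence = sequence
        self.ca = np.array(ca, dtype=float).reshape(n, 3)
        self.cb = np.array(cb, dtype=float).reshape(n, 3)
        self.o = np.array(o, dtype=float).reshape(n, 3)
        gly = np.array([c == "G" for c in sequence])
        self.cb[gly] = np.nan
        if np.isnan(self.ca).any() or np.isnan(self.o).any():
            raise TopologyError("Calpha/O coordinates must be finite")
        if np.isnan(self.cb[~gly]).any():
            raise TopologyError("non-glycine residues must supply Cbeta")
        self.has_cb = ~gly
        self.charges = np.array([RESIDUE_CHARGE.get(c, 0) for c in sequence],
                                dtype=float)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def residues(self) -> list[ResidueBead]:
        n = self.n_residues
        return [ResidueBead(
            index=i + 1, aa=self.sequence[i], ca=self.ca[i],
            cb=(self.cb[i] if self.has_cb[i] else None), o=self.o[i],
            charge=int(self.charges[i]), is_terminal=(i == 0 or i == n - 1))
            for i in range(n)]

    def copy(self) -> "CoarseProtein":
        return CoarseProtein(self.sequence, self.ca.copy(),
                             np.nan_to_num(self.cb, nan=0.0), self.o.copy())

    def bead_masses(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(m_ca, m_cb, m_o): residue mass lumped onto the three beads."""
        m_ca = np.full(self.n_residues, 56.0)
        m_o = np.full(self.n_residues, 16.0)
        m_cb = np.array([_SIDECHAIN_MASS[c] for c in self.sequence])
        return m_ca, m_cb, m_o


@dataclass
class HemeAtom:
    name: str
    element: str
    xyz: np.ndarray
    partial_charge: float
    role: str  # FE | N_PYRROLE | O_CARBOXYL | C_VINYL | OTHER


class Heme:
    """All-atom heme cofactor with internal bonded topology.

    Bond and angle equilibria are taken from the geometry the heme was
    built or read with (a knowledge-based native reference); dihedral
    phases are chosen so that the reference geometry is a torsional
    minimum.
    """

    def __init__(self, names: Sequence[str], xyz: np.ndarray,
                 heme_type: str, params: ParameterSet,
                 role_map: Mapping[str, str] | None = None):
        if heme_type not in ("b", "c"):
            raise TopologyError(f"heme_type must be 'b' or 'c', got {heme_type!r}")
        role_map = dict(DEFAULT_ROLE_MAP if role_map is None else role_map)
        self.names = [str(n).upper() for n in names]
        self.xyz = np.array(xyz, dtype=float).reshape(len(names), 3)
        self.heme_type = heme_type
        self.roles = [role_map.get(n, "OTHER") for n in self.names]
        self.elements = [("FE" if n.startswith("FE") else n[0]) for n in self.names]
        self.partial_charges = np.array(
            [params.heme_charges.get(n, 0.0) for n in self.names])
        total = self.partial_charges.sum()
        if abs(total - params.heme_formal_charge) > 1e-6:
            raise TopologyError(
                f"heme partial charges sum to {total:.6f}, expected "
                f"{params.heme_formal_charge:.6f}; unknown atom names "
                f"{sorted(set(self.names) - set(params.heme_charges))!r}")
        self._check_roles()
        self._index = {n: i for i, n in enumerate(self.names)}
        self.lj_sigma = np.array(
            [params.heme_lj[e]["sigma"] for e in self.elements])
        self.lj_epsilon = np.array(
            [params.heme_lj[e]["epsilon"] for e in self.elements])
        self.masses = np.array([_ELEMENT_MASS[e] for e in self.elements])
        self._build_topology(params)

    # -- construction helpers -------------------------------------------
    def _check_roles(self) -> None:
        counts = {r: self.roles.count(r) for r in
                  ("FE", "N_PYRROLE", "O_CARBOXYL", "C_VINYL")}
        expected = {"FE": 1, "N_PYRROLE": 4, "O_CARBOXYL": 4, "C_VINYL": 2}
        if counts != expected:
            raise TopologyError(
                f"heme role counts {counts} do not match required {expected}")

    def _build_topology(self, params: ParameterSet) -> None:
        from .geometry import angle, dihedral

        n = len(self.names)
        pairs = set()
        for a, b in HEME_BOND_TEMPLATE:
            if a in self._index and b in self._index:
                i, j = self._index[a], self._index[b]
                pairs.add((min(i, j), max(i, j)))
        bonded_atoms = {i for p in pairs for i in p}
        # orphan atoms (nonstandard names): attach to nearest neighbour
        for i in range(n):
            if i not in bonded_atoms:
                d = np.linalg.norm(self.xyz - self.xyz[i], axis=1)
                d[i] = np.inf
                j = int(np.argmin(d))
                pairs.add((min(i, j), max(i, j)))
        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j in pairs:
            adj[i].add(j)
            adj[j].add(i)

        self.bonds = [(i, j, params.heme_bond_k,
                       float(np.linalg.norm(self.xyz[i] - self.xyz[j])))
                      for i, j in sorted(pairs)]
        angles = []
        for j in range(n):
            nb = sorted(adj[j])
            for a in range(len(nb)):
                for b in range(a + 1, len(nb)):
                    i, k = nb[a], nb[b]
                    th0 = float(angle(self.xyz[i], self.xyz[j], self.xyz[k]))
                    angles.append((i, j, k, params.heme_angle_k, th0))
        self.angles = angles
        dihedrals = []
        seen = set()
        for j, k in sorted(pairs):
            for i in adj[j] - {k}:
                for l in adj[k] - {j}:
                    if i == l:
                        continue
                    key = (i, j, k, l) if (j, k, i, l) <= (k, j, l, i) else (l, k, j, i)
                    if key in seen:
                        continue
                    seen.add(key)
                    # a torsion across a (near-)collinear triple is
                    # undefined (e.g. trans N-Fe-N in the porphyrin):
                    # exclude it rather than restrain numerical noise
                    b1 = self.xyz[j] - self.xyz[i]
                    b2 = self.xyz[k] - self.xyz[j]
                    b3 = self.xyz[l] - self.xyz[k]
                    n1 = np.cross(b1, b2)
                    n2 = np.cross(b2, b3)
                    min_area = 0.1 * min(
                        np.linalg.norm(b1) * np.linalg.norm(b2),
                        np.linalg.norm(b2) * np.linalg.norm(b3))
                    if min(np.linalg.norm(n1), np.linalg.norm(n2)) < min_area:
                        continue
                    phi0 = float(dihedral(self.xyz[i], self.xyz[j],
                                          self.xyz[k], self.xyz[l]))
                    # k (1 + cos(2 phi - gamma)) vanishes at phi0
                    gamma = 2.0 * phi0 - np.pi
                    dihedrals.append((i, j, k, l, params.heme_dihedral_k,
                                      2, gamma))
        self.dihedrals = dihedrals
        # nonbonded exclusions: 1-2 and 1-3 excluded, 1-4 scaled
        excl = set(pairs)
        for (i, j, k, _, _) in self.angles:
            excl.add((min(i, k), max(i, k)))
        scaled = set()
        for (i, j, k, l, *_ ) in self.dihedrals:
            p = (min(i, l), max(i, l))
            if p not in excl:
                scaled.add(p)
        self.excluded_pairs = excl
        self.scaled_pairs = scaled
        self._build_arrays(params)

    def _build_arrays(self, params: ParameterSet) -> None:
        """Flat topology arrays for vectorized energy evaluation."""
        def cols(rows, width):
            if not rows:
                return [np.empty(0, dtype=(int if c < width - 2 else float))
                        for c in range(width)]
            return [np.array(c) for c in zip(*rows)]

        self.bond_arrays = cols(self.bonds, 4)
        self.angle_arrays = cols(self.angles, 5)
        if self.dihedrals:
            i, j, k, l, kf, n, gam = zip(*self.dihedrals)
            self.dihedral_arrays = (np.array(i), np.array(j), np.array(k),
                                    np.array(l), np.array(kf),
                                    np.array(n, dtype=float), np.array(gam))
        else:
            self.dihedral_arrays = tuple(np.empty(0) for _ in range(7))
        iu, ju = np.triu_indices(self.n_atoms, k=1)
        keep = np.array([(a, b) not in self.excluded_pairs
                         for a, b in zip(iu, ju)])
        iu, ju = iu[keep], ju[keep]
        scaled = np.array([(a, b) in self.scaled_pairs
                           for a, b in zip(iu, ju)])
        self.nb_arrays = {
            "i": iu, "j": ju,
            "scale_lj": np.where(scaled, params.scale14_lj, 1.0),
            "scale_c": np.where(scaled, params.scale14_coulomb, 1.0),
            "sigma": 0.5 * (self.lj_sigma[iu] + self.lj_sigma[ju]),
            "epsilon": np.sqrt(self.lj_epsilon[iu] * self.lj_epsilon[ju]),
            "qq": self.partial_charges[iu] * self.partial_charges[ju],
        }

    # -- basic API -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def atoms(self) -> list[HemeAtom]:
        return [HemeAtom(self.names[i], self.elements[i], self.xyz[i],
                         float(self.partial_charges[i]), self.roles[i])
                for i in range(self.n_atoms)]

    def atoms_with_role(self, role: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r == role],
                        dtype=int)

    @property
    def fe_index(self) -> int:
        return int(self.atoms_with_role("FE")[0])

    def plane_normal(self) -> np.ndarray:
        """Unit normal of the best-fit plane through the pyrrole nitrogens."""
        idx = self.atoms_with_role("N_PYRROLE")
        pts = self.xyz[idx] - self.xyz[idx].mean(axis=0)
        _, _, vt = np.linalg.svd(pts)
        return vt[2]


@dataclass
class DistalRestraint:
    """Marks one axial face of the heme as occupied by a distal ligand.

    Residues approaching the blocked face are excluded from the Fe
    coordinate-covalent term; ``k`` is the spring constant used when an
    explicit dummy ligand particle is tethered to that face.
    """
    face: int          # +1 or -1: sign of (Cbeta - Fe) . plane_normal
    k: float = 1000.0  # kJ/mol/nm^2


class SystemState:
    """A coarse protein plus (optionally) one heme cofactor."""

    def __init__(self, protein: CoarseProtein, heme: Heme | None = None,
                 distal_restraint: DistalRestraint | None = None,
                 cys_attachments: tuple[int, int] | None = None):
        self.protein = protein
        self.heme = heme
        self.distal_restraint = distal_restraint
        if heme is not None and heme.heme_type == "c":
            if cys_attachments is None:
                cys_attachments = find_cxxc(protein)
            i, j = cys_attachments
            if j - i != 3:
                raise TopologyError(
                    "heme c attachment cysteines must be separated by two "
                    f"residues (CXXC), got indices {i}, {j}")
            for k in (i, j):
                if protein.sequence[k - 1] != "C":
                    raise TopologyError(f"residue {k} is not a cysteine")
        self.cys_attachments = cys_attachments

    # -- flat coordinate packing for dynamics ---------------------------
    def _layout(self):
        n = self.protein.n_residues
        cb_idx = np.flatnonzero(self.protein.has_cb)
        n_heme = 0 if self.heme is None else self.heme.n_atoms
        return n, cb_idx, n_heme

    @property
    def n_particles(self) -> int:
        n, cb_idx, n_heme = self._layout()
        return 2 * n + len(cb_idx) + n_heme

    def get_coords(self) -> np.ndarray:
        n, cb_idx, _ = self._layout()
        parts = [self.protein.ca, self.protein.cb[cb_idx], self.protein.o]
        if self.heme is not None:
            parts.append(self.heme.xyz)
        return np.concatenate(parts, axis=0)

    def set_coords(self, coords: np.ndarray) -> None:
        n, cb_idx, n_heme = self._layout()
        coords = np.asarray(coords, dtype=float)
        self.protein.ca[:] = coords[:n]
        self.protein.cb[cb_idx] = coords[n:n + len(cb_idx)]
        self.protein.o[:] = coords[n + len(cb_idx):2 * n + len(cb_idx)]
        if self.heme is not None:
            self.heme.xyz[:] = coords[2 * n + len(cb_idx):]

    def particle_masses(self) -> np.ndarray:
        n, cb_idx, _ = self._layout()
        m_ca, m_cb, m_o = self.protein.bead_masses()
        parts = [m_ca, m_cb[cb_idx], m_o]
        if self.heme is not None:
            parts.append(self.heme.masses)
        return np.concatenate(parts)

    def copy(self) -> "SystemState":
        import copy as _copy
        return _copy.deepcopy(self)


def find_cxxc(protein: CoarseProtein) -> tuple[int, int]:
    """Locate the CXXC attachment motif; 1-based residue indices.

    Raises :class:`TopologyError` unless exactly one pair of cysteines
    separated by two residues exists.
    """
    seq = protein.sequence
    hits = [(i + 1, i + 4) for i in range(len(seq) - 3)
            if seq[i] == "C" and seq[i + 3] == "C"]
    if len(hits) != 1:
        raise TopologyError(
            f"expected exactly one CXXC motif for heme c, found {len(hits)}")
    return hits[0]


# ---------------------------------------------------------------------------
# Coarse-graining and backbone reconstruction
# ---------------------------------------------------------------------------

def coarse_grain(full_atoms: Iterable[tuple[str, Mapping[str, np.ndarray]]]
                 ) -> CoarseProtein:
    """Build a :class:`CoarseProtein` from per-residue atom coordinates.

    ``full_atoms`` yields ``(three_letter_name, {atom_name: xyz_nm})`` in
    chain order.  Every residue must supply CA and O; CB is required
    unless the residue is glycine.
    """
    seq = []
    ca, cb, o = [], [], []
    for ordinal, (resname, atoms) in enumerate(full_atoms, start=1):
        resname = resname.upper()
        if resname not in THREE_TO_ONE:
            raise PDBParseError(f"unknown residue name {resname!r} at ordinal {ordinal}")
        one = THREE_TO_ONE[resname]
        for needed in ("CA", "O"):
            if needed not in atoms:
                raise PDBParseError(
                    f"residue {ordinal} ({resname}) is missing atom {needed}")
        if one != "G" and "CB" not in atoms:
            raise PDBParseError(
                f"non-glycine residue {ordinal} ({resname}) is missing CB")
        seq.append(one)
        ca.append(np.asarray(atoms["CA"], dtype=float))
        o.append(np.asarray(atoms["O"], dtype=float))
        cb.append(np.asarray(atoms.get("CB", atoms["CA"]), dtype=float))
    return CoarseProtein("".join(seq), np.array(ca), np.array(cb), np.array(o))


def reconstruct_backbone(protein: CoarseProtein,
                         params: ParameterSet | None = None):
    """Ideal-geometry virtual backbone sites N, H, C as (N, 3) arrays.

    N and H of residue i are affine combinations of Calpha(i-1),
    Calpha(i) and O(i-1); C of residue i combines Calpha(i),
    Calpha(i+1) and O(i).  Undefined rows (N/H of the first residue, C
    of the last) are NaN.  Because each coefficient triple sums to 1 the
    sites are exactly equivariant under rigid motions.
    """
    if protein.n_residues < 2:
        raise TopologyError("backbone reconstruction needs at least 2 residues")
    if params is None:
        params = load_parameters()
    vs = params.virtual_sites
    n = protein.n_residues
    out = {}
    for site in ("N", "H"):
        c = vs[site]
        arr = np.full((n, 3), np.nan)
        arr[1:] = (c["ca_prev"] * protein.ca[:-1]
                   + c["ca"] * protein.ca[1:]
                   + c["o_prev"] * protein.o[:-1])
        out[site] = arr
    c = vs["C"]
    arr = np.full((n, 3), np.nan)
    arr[:-1] = (c["ca"] * protein.ca[:-1]
                + c["ca_next"] * protein.ca[1:]
                + c["o"] * protein.o[:-1])
    out["C"] = arr
    return out["N"], out["H"], out["C"]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    """Cheap validation pass so parse errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(
                        f"{path.name}:{lineno}: truncated coordinate record")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError as exc:
                    raise PDBParseError(
                        f"{path.name}:{lineno}: unparseable coordinates") from exc


def read_pdb(path: str | Path, heme_resnames: Iterable[str] = ("HEM", "HEC"),
             params: ParameterSet | None = None,
             role_map: Mapping[str, str] | None = None) -> SystemState:
    """Read a PDB file into a :class:`SystemState` (nm internally).

    The first protein chain is coarse-grained; at most one heme
    heterogroup (resname in ``heme_resnames``) is accepted, with HEC
    mapped to heme type c and anything else to type b.  Alternate
    locations beyond the first are discarded.
    """
    path = Path(path)
    _prescan_pdb(path)
    if params is None:
        params = load_parameters()
    arr = PDBFile.read(str(path)).get_structure(model=1, altloc="first")

    aa_mask = struc.filter_amino_acids(arr)
    if not aa_mask.any():
        raise PDBParseError(f"{path.name}: no protein chain found")
    prot = arr[aa_mask]
    first_chain = prot.chain_id[0]
    prot = prot[prot.chain_id == first_chain]

    residues = []
    starts = struc.get_residue_starts(prot, add_exclusive_stop=True)
    for s, e in zip(starts[:-1], starts[1:]):
        res = prot[s:e]
        atoms = {res.atom_name[i]: res.coord[i] * 0.1 for i in range(len(res))}
        residues.append((res.res_name[0], atoms))
    protein = coarse_grain(residues)

    heme_resnames = {r.upper() for r in heme_resnames}
    het = arr[np.isin(arr.res_name, sorted(heme_resnames))]
    heme = None
    if len(het) > 0:
        res_ids = sorted(set(zip(het.chain_id, het.res_id)))
        if len(res_ids) > 1:
            raise TopologyError(
                f"{path.name}: found {len(res_ids)} heme groups, expected at most 1")
        heme_type = "c" if het.res_name[0].upper() == "HEC" else "b"
        heme = Heme(list(het.atom_name), het.coord * 0.1, heme_type, params,
                    role_map=role_map)
    return SystemState(protein, heme)


def write_pdb(state: SystemState, path: str | Path) -> None:
    """Write a :class:`SystemState` as a standard PDB file (Angstrom)."""
    protein = state.protein
    if protein.n_residues == 0:
        raise ValueError("refusing to write an empty protein")
    records = []
    n_atoms = int(2 * protein.n_residues + protein.has_cb.sum())
    if state.heme is not None:
        n_atoms += state.heme.n_atoms
    atoms = struc.AtomArray(n_atoms)
    k = 0
    for i in range(protein.n_residues):
        one = protein.sequence[i]
        triple = [("CA", "C", protein.ca[i]), ("O", "O", protein.o[i])]
        if protein.has_cb[i]:
            triple.insert(1, ("CB", "C", protein.cb[i]))
        for name, element, xyz in triple:
            atoms.coord[k] = xyz * 10.0
            atoms.atom_name[k] = name
            atoms.element[k] = element
            atoms.res_id[k] = i + 1
            atoms.res_name[k] = ONE_TO_THREE[one]
            atoms.chain_id[k] = "A"
            atoms.hetero[k] = False
            k += 1
    if state.heme is not None:
        heme = state.heme
        resname = "HEC" if heme.heme_type == "c" else "HEM"
        for i in range(heme.n_atoms):
            atoms.coord[k] = heme.xyz[i] * 10.0
            atoms.atom_name[k] = heme.names[i]
            atoms.element[k] = "FE" if heme.elements[i] == "FE" else heme.elements[i]
            atoms.res_id[k] = protein.n_residues + 1
            atoms.res_name[k] = resname
            atoms.chain_id[k] = "B"
            atoms.hetero[k] = True
            k += 1
    pdbf = PDBFile()
    pdbf.set_structure(atoms)
    pdbf.write(str(path))
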