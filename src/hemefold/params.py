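"""Parameter handling.

All coupling constants, equilibrium geometries and cutoffs of the hybrid
model live in a single YAML document.  The loader is strict: a missing key
is an error, never a silent default, so that a parameter file fully
determines the Hamiltonian being evaluated.

Units: lengths nm, energies kJ/mol, angles radians, charges e.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Boltzmann constant in kJ/mol/K (MD unit system: nm, ps, amu, kJ/mol).
KB = 0.008314462618


class ParameterError(ValueError):
    """Raised when a parameter file is missing keys or holds invalid values."""


@dataclass
class ParameterSet:
    """Every tunable constant of the hybrid Hamiltonian.

    Per-residue tables (``lambda_fe_cc``, ``lambda_hb_sidechain``,
    ``r_hb_sidechain``) are keyed by one-letter amino-acid code and must
    cover all twenty residue types.
    """

    # Fe coordinate-covalent restraint
    lambda_fe_cc: dict[str, float]
    r_fe_cc: float
    theta_fe_cc: float
    fe_cc_exponent_sign: int
    # screened electrostatics
    lambda_elec: float
    k_screening: float
    l_screening: float
    # backbone hydrogen bond
    lambda_hb_backbone: float
    r_hb: float
    theta_hb: float
    # sidechain hydrogen bond
    lambda_hb_sidechain: dict[str, float]
    r_hb_sidechain: dict[str, float]
    # carboxylate burial penalty
    lambda_burial: float
    r_burial: float
    # excluded volume
    lambda_excl: float
    r_excl: float
    # thioester tether (heme c)
    lambda_cs: float
    r_thioester: float
    # pocket-contact cutoff for Q_c
    qc_cutoff: float
    # ideal-geometry virtual-site coefficients
    virtual_sites: dict[str, dict[str, float]]
    # internal heme forcefield
    heme_formal_charge: float
    heme_charges: dict[str, float]
    heme_lj: dict[str, dict[str, float]]
    heme_bond_k: float
    heme_angle_k: float
    heme_dihedral_k: float
    coulomb_constant: float
    dielectric: float
    scale14_lj: float
    scale14_coulomb: float
    # structure-based protein stand-in
    standin_epsilon: float
    standin_width: float
    standin_bond_k: float
    standin_chirality_k: float
    standin_pair_cutoff: float
    # truncation of Gaussian coupling terms
    truncation_cutoff: float
    source: str = field(default="<memory>", compare=False)

    def file_hash(self) -> str:
        """SHA-256 of the source file, or of the repr for in-memory sets."""
        p = Path(self.source)
        if p.is_file():
            return hashlib.sha256(p.read_bytes()).hexdigest()
        return hashlib.sha256(repr(self).encode()).hexdigest()


def _require(mapping: Mapping[str, Any], key: str, ctx: str) -> Any:
    if not isinstance(mapping, Mapping) or key not in mapping:
        raise ParameterError(f"parameter file is missing required key {ctx!r}.{key!r}")
    return mapping[key]


def _residue_table(raw: Mapping[str, Any], ctx: str) -> dict[str, float]:
    table = {}
    for aa in AMINO_ACIDS:
        table[aa] = float(_require(raw, aa, ctx))
    return table


def _validate(ps: ParameterSet) -> ParameterSet:
    for name in ("r_fe_cc", "r_hb", "r_burial", "r_excl", "r_thioester",
                 "qc_cutoff", "l_screening", "truncation_cutoff",
                 "standin_width", "standin_pair_cutoff"):
        if getattr(ps, name) <= 0:
            raise ParameterError(f"{name} must be positive, got {getattr(ps, name)}")
    if ps.fe_cc_exponent_sign not in (-1, 1):
        raise ParameterError("fe_cc.exponent_sign must be -1 or +1")
    total = sum(ps.heme_charges.values())
    if abs(total - ps.heme_formal_charge) > 1e-6:
        raise ParameterError(
            f"heme partial charges sum to {total:.6f}, "
            f"declared formal charge is {ps.heme_formal_charge:.6f}")
    return ps


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load a parameter file; ``None`` loads the packaged defaults.

    Raises :class:`ParameterError` on any missing key — the model never
    invents a value the file does not state.
    """
    if path is None:
        ref = resources.files("hemefold.data") / "default_params.yaml"
        text = ref.read_text()
        source = str(ref)
    else:
        text = Path(path).read_text()
        source = str(path)
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ParameterError(f"parameter file {source!r} is not a mapping")

    fe = _require(raw, "fe_cc", "")
    el = _require(raw, "elec", "")
    hbb = _require(raw, "hb_backbone", "")
    hbs = _require(raw, "hb_sidechain", "")
    bur = _require(raw, "burial", "")
    exc = _require(raw, "excl", "")
    thio = _require(raw, "thioester", "")
    vs = _require(raw, "backbone_virtual_sites", "")
    heme = _require(raw, "heme", "")
    standin = _require(raw, "standin", "")

    sites = {}
    for site, keys in (("N", ("ca_prev", "ca", "o_prev")),
                       ("H", ("ca_prev", "ca", "o_prev")),
                       ("C", ("ca", "ca_next", "o"))):
        entry = _require(vs, site, "backbone_virtual_sites")
        coeffs = {k: float(_require(entry, k, f"backbone_virtual_sites.{site}"))
                  for k in keys}
        # virtual sites must be affine combinations (coefficients sum to
        # 1) to be rigid-motion equivariant; renormalize rounding-level
        # deviations, reject anything larger
        total = sum(coeffs.values())
        if abs(total - 1.0) > 1e-3:
            raise ParameterError(
                f"backbone_virtual_sites.{site} coefficients sum to "
                f"{total:.6f}, must be 1 (affine)")
        sites[site] = {k: v / total for k, v in coeffs.items()}

    lj = {}
    for element, entry in _require(heme, "lj", "heme").items():
        lj[element] = {"sigma": float(_require(entry, "sigma", f"heme.lj.{element}")),
                       "epsilon": float(_require(entry, "epsilon", f"heme.lj.{element}"))}

    ps = ParameterSet(
        lambda_fe_cc=_residue_table(_require(fe, "lambda", "fe_cc"), "fe_cc.lambda"),
        r_fe_cc=float(_require(fe, "r0", "fe_cc")),
        theta_fe_cc=float(_require(fe, "theta0", "fe_cc")),
        fe_cc_exponent_sign=int(_require(fe, "exponent_sign", "fe_cc")),
        lambda_elec=float(_require(el, "lambda", "elec")),
        k_screening=float(_require(el, "k_screening", "elec")),
        l_screening=float(_require(el, "l_screening", "elec")),
        lambda_hb_backbone=float(_require(hbb, "lambda", "hb_backbone")),
        r_hb=float(_require(hbb, "r0", "hb_backbone")),
        theta_hb=float(_require(hbb, "theta0", "hb_backbone")),
        lambda_hb_sidechain=_residue_table(_require(hbs, "lambda", "hb_sidechain"),
                                           "hb_sidechain.lambda"),
        r_hb_sidechain=_residue_table(_require(hbs, "r0", "hb_sidechain"),
                                      "hb_sidechain.r0"),
        lambda_burial=float(_require(bur, "lambda", "burial")),
        r_burial=float(_require(bur, "r0", "burial")),
        lambda_excl=float(_require(exc, "lambda", "excl")),
        r_excl=float(_require(exc, "r0", "excl")),
        lambda_cs=float(_require(thio, "lambda_cs", "thioester")),
        r_thioester=float(_require(thio, "r0", "thioester")),
        qc_cutoff=float(_require(raw, "qc_cutoff", "")),
        virtual_sites=sites,
        heme_formal_charge=float(_require(heme, "formal_charge", "heme")),
        heme_charges={k: float(v) for k, v in _require(heme, "charges", "heme").items()},
        heme_lj=lj,
        heme_bond_k=float(_require(heme, "bond_k", "heme")),
        heme_angle_k=float(_require(heme, "angle_k", "heme")),
        heme_dihedral_k=float(_require(heme, "dihedral_k", "heme")),
        coulomb_constant=float(_require(heme, "coulomb_constant", "heme")),
        dielectric=float(_require(heme, "dielectric", "heme")),
        scale14_lj=float(_require(heme, "scale14_lj", "heme")),
        scale14_coulomb=float(_require(heme, "scale14_coulomb", "heme")),
        standin_epsilon=float(_require(standin, "epsilon", "standin")),
        standin_width=float(_require(standin, "width", "standin")),
        standin_bond_k=float(_require(standin, "bond_k", "standin")),
        standin_chirality_k=float(_require(standin, "chirality_k", "standin")),
        standin_pair_cutoff=float(_require(standin, "pair_cutoff", "standin")),
        truncation_cutoff=float(_require(raw, "truncation_cutoff", "")),
        source=source,
    )
    return _validate(ps)
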