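"""Structural similarity metrics.

``q_w`` scores the protein against a reference through Gaussian-weighted
agreement of all Calpha-Calpha distances with sequence separation > 2,

    Q_w = 2 / ((N-2)(N-3)) * sum_{j-i>2} exp(-(r_ij - r_ij^N)^2 / (2 s_ij^2)),
    s_ij = |j - i|^0.15,

so identical structures score exactly 1.  ``q_c`` scores the heme pocket:
the fraction of native heme-protein contacts (any heme atom within the
cutoff of a residue's Cbeta, 0.65 nm by default) that are reproduced.
``rmsd`` is the Kabsch-superposed Calpha deviation.
"""

from __future__ import annotations

import numpy as np

from .geometry import kabsch
from .model_io import CoarseProtein, SystemState

__all__ = ["q_w", "q_w_gradient", "q_c", "contact_residues", "rmsd",
           "per_residue_rmsd"]

SIGMA_EXPONENT = 0.15
#: The separation-dependent well width |j-i|^0.15 is measured in Angstrom
#: (0.1 nm); in nm the metric would barely distinguish a coil from the
#: native fold.
SIGMA_SCALE = 0.1  # nm per Angstrom


def _pair_indices(n: int):
    iu, ju = np.triu_indices(n, k=3)
    return iu, ju


def _check_pair(pred: CoarseProtein, ref: CoarseProtein) -> int:
    if pred.n_residues != ref.n_residues:
        raise ValueError(
            f"length mismatch: {pred.n_residues} vs {ref.n_residues}")
    n = pred.n_residues
    if n < 4:
        raise ValueError("q_w needs at least 4 residues")
    return n


def q_w(pred: CoarseProtein, ref: CoarseProtein) -> float:
    """Gaussian-weighted fraction of native Calpha distances, in (0, 1]."""
    n = _check_pair(pred, ref)
    iu, ju = _pair_indices(n)
    r = np.linalg.norm(pred.ca[iu] - pred.ca[ju], axis=1)
    r0 = np.linalg.norm(ref.ca[iu] - ref.ca[ju], axis=1)
    sig = SIGMA_SCALE * (ju - iu).astype(float) ** SIGMA_EXPONENT
    w = np.exp(-(r - r0) ** 2 / (2.0 * sig ** 2))
    return float(2.0 * w.sum() / ((n - 2) * (n - 3)))


def q_w_gradient(ca: np.ndarray, ref_ca: np.ndarray):
    """``(Q_w, dQ_w/dCalpha)`` for umbrella biasing on Q_w.

    The gradient runs over every included pair; each pair contributes
    ``-(r - r0)/s^2 * w`` along the unit separation vector.
    """
    n = len(ca)
    iu, ju = _pair_indices(n)
    diff = ca[iu] - ca[ju]
    r = np.linalg.norm(diff, axis=1)
    r0 = np.linalg.norm(ref_ca[iu] - ref_ca[ju], axis=1)
    sig2 = SIGMA_SCALE ** 2 * (ju - iu).astype(float) ** (2 * SIGMA_EXPONENT)
    w = np.exp(-(r - r0) ** 2 / (2.0 * sig2))
    norm = 2.0 / ((n - 2) * (n - 3))
    qw = float(norm * w.sum())
    coef = norm * (-(r - r0) / sig2) * w / r
    grad = np.zeros((n, 3))
    vec = coef[:, None] * diff
    np.add.at(grad, iu, vec)
    np.add.at(grad, ju, -vec)
    return qw, grad


def contact_residues(state: SystemState, cutoff: float) -> set[int]:
    """1-based indices of residues whose Cbeta lies within ``cutoff`` of
    any heme atom.  Glycine, having no Cbeta, can never contact."""
    if state.heme is None:
        raise ValueError("state has no heme")
    idx = np.flatnonzero(state.protein.has_cb)
    cb = state.protein.cb[idx]
    d = np.linalg.norm(cb[:, None, :] - state.heme.xyz[None, :, :], axis=2)
    hit = (d < cutoff).any(axis=1)
    return {int(i) + 1 for i in idx[hit]}


def _contact_pairs(state: SystemState, cutoff: float) -> set[tuple[int, int]]:
    idx = np.flatnonzero(state.protein.has_cb)
    cb = state.protein.cb[idx]
    d = np.linalg.norm(cb[:, None, :] - state.heme.xyz[None, :, :], axis=2)
    ii, jj = np.nonzero(d < cutoff)
    return {(int(idx[a]) + 1, int(b)) for a, b in zip(ii, jj)}


def q_c(pred: SystemState, ref: SystemState, cutoff: float = 0.65,
        mode: str = "residue") -> float:
    """Fraction of native heme-pocket contacts reproduced, in [0, 1].

    ``mode='residue'`` counts a residue as in contact if any heme atom
    is within ``cutoff`` of its Cbeta; ``mode='atom'`` counts individual
    (residue, heme-atom) pairs.  Only contacts present in the reference
    are credited, so the score is not symmetric in its arguments.
    """
    if pred.heme is None or ref.heme is None:
        raise ValueError("both states must contain a heme")
    if pred.protein.n_residues != ref.protein.n_residues:
        raise ValueError("residue numbering mismatch")
    finder = contact_residues if mode == "residue" else _contact_pairs
    if mode not in ("residue", "atom"):
        raise ValueError(f"unknown contact mode {mode!r}")
    native = finder(ref, cutoff)
    if not native:
        raise ValueError("reference structure has no heme-protein contacts")
    found = finder(pred, cutoff)
    return len(native & found) / len(native)


def rmsd(pred: CoarseProtein, ref: CoarseProtein, align: bool = True) -> float:
    """Calpha RMSD (nm), after optimal rigid superposition if ``align``."""
    _check_pair(pred, ref)
    if align:
        _, _, value = kabsch(pred.ca, ref.ca)
        return value
    return float(np.sqrt(np.mean(np.sum((pred.ca - ref.ca) ** 2, axis=1))))


def per_residue_rmsd(pred: CoarseProtein, ref: CoarseProtein) -> np.ndarray:
    """Per-residue Calpha deviation (nm) after global superposition,
    for structure colouring."""
    _check_pair(pred, ref)
    aligned, _, _ = kabsch(pred.ca, ref.ca)
    return np.linalg.norm(aligned - ref.ca, axis=1)
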