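"""Vector geometry: distances, angles, dihedrals and their gradients.

All gradient formulas are analytic and are cross-checked against central
finite differences in the test suite.  Arrays are (..., 3) and operations
broadcast over leading axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "distances", "angle", "angle_grad", "dihedral", "dihedral_grad",
    "kabsch", "random_rotation",
]


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product over the last axis; avoids np.cross's moveaxis
    overhead on small arrays (hot path)."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    a0, a1, a2 = a[..., 0], a[..., 1], a[..., 2]
    b0, b1, b2 = b[..., 0], b[..., 1], b[..., 2]
    out[..., 0] = a1 * b2 - a2 * b1
    out[..., 1] = a2 * b0 - a0 * b2
    out[..., 2] = a0 * b1 - a1 * b0
    return out


def _vnorm(a: np.ndarray, keepdims: bool = False) -> np.ndarray:
    """Euclidean norm over the last axis (cheaper than linalg.norm)."""
    out = np.sqrt(np.einsum("...i,...i->...", a, a))
    if keepdims:
        out = out[..., None]
    return out


def distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean norms of a - b along the last axis."""
    return _vnorm(a - b)


def angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Angle at vertex p2 spanned by p1 and p3, in [0, pi]."""
    u = p1 - p2
    v = p3 - p2
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    c = np.sum(u * v, axis=-1) / (nu * nv)
    return np.arccos(np.clip(c, -1.0, 1.0))


def angle_grad(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray):
    """Angle at vertex p2 plus gradients w.r.t. the three points.

    Returns ``(theta, g1, g2, g3)`` with ``gk = d theta / d pk``.  The
    gradient is undefined for collinear points; a floor on sin(theta)
    keeps it finite (such configurations carry vanishing statistical
    weight in the potentials that use this).
    """
    u = p1 - p2
    v = p3 - p2
    nu = _vnorm(u, keepdims=True)
    nv = _vnorm(v, keepdims=True)
    uh = u / nu
    vh = v / nv
    c = np.clip(np.sum(uh * vh, axis=-1, keepdims=True), -1.0, 1.0)
    theta = np.arccos(c[..., 0])
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-12))
    g1 = (c * uh - vh) / (nu * s)
    g3 = (c * vh - uh) / (nv * s)
    g2 = -(g1 + g3)
    return theta, g1, g2, g3


def dihedral(p1, p2, p3, p4) -> np.ndarray:
    """Signed dihedral angle of the chain p1-p2-p3-p4, in (-pi, pi]."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    b2h = b2 / _vnorm(b2, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(_cross(n1, n2) * b2h, axis=-1)
    return np.arctan2(y, x)


def dihedral_grad(p1, p2, p3, p4):
    """Dihedral angle plus gradients w.r.t. the four points."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    nb2 = _vnorm(b2, keepdims=True)
    n1sq = np.maximum(np.sum(n1 * n1, axis=-1, keepdims=True), 1e-18)
    n2sq = np.maximum(np.sum(n2 * n2, axis=-1, keepdims=True), 1e-18)
    phi = dihedral(p1, p2, p3, p4)
    g1 = -nb2 / n1sq * n1
    g4 = nb2 / n2sq * n2
    d12 = np.sum(b1 * b2, axis=-1, keepdims=True) / (nb2 * nb2)
    d32 = np.sum(b3 * b2, axis=-1, keepdims=True) / (nb2 * nb2)
    g2 = -(1.0 + d12) * g1 + d32 * g4
    g3 = d12 * g1 - (1.0 + d32) * g4
    return phi, g1, g2, g3, g4


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(aligned, rotation, rmsd)`` where ``aligned`` is the
    transformed mobile set.  Proper rotations only (no reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    a = mobile - mc
    b = target - tc
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.diag([1.0, 1.0, d])
    rot = u @ flip @ vt
    aligned = a @ rot + tc
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - target) ** 2, axis=-1))))
    return aligned, rot, rmsd


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
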