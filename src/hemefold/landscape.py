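"""Free-energy surfaces from trajectories and umbrella windows.

Unbiased surfaces are histogram estimates, F = -kT ln P, reported in kT
units relative to the global minimum with empty bins masked.  Biased
umbrella windows along Q_w are recombined with the standard binned
self-consistent WHAM iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory, UmbrellaWindow
from .params import KB

__all__ = ["FreeEnergySurface", "FreeEnergyProfile", "fes_2d", "fes_1d",
           "wham", "basin_report", "Basin"]


@dataclass
class FreeEnergySurface:
    """Binned 2D free-energy surface in kT units.

    ``f`` is NaN on unpopulated bins and is shifted so its minimum over
    populated bins is zero.
    """
    x_name: str
    y_name: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    f: np.ndarray            # (nx, ny), kT units, NaN where empty
    counts: np.ndarray
    temperature: float

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def to_table(self):
        """Flat records (x_center, y_center, F_kT, count) for CSV export."""
        rows = []
        for i, xc in enumerate(self.x_centers):
            for j, yc in enumerate(self.y_centers):
                rows.append((float(xc), float(yc), float(self.f[i, j]),
                             int(self.counts[i, j])))
        return rows


@dataclass
class FreeEnergyProfile:
    """1D free-energy profile in kT units over a scalar coordinate."""
    coordinate: str
    centers: np.ndarray
    f: np.ndarray            # NaN where unsampled
    temperature: float


def _edges(values: np.ndarray, bins: int, pad: float = 0.05) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    span = hi - lo
    if span == 0:
        span = max(abs(hi), 1.0) * 1e-6
    return np.linspace(lo - pad * span, hi + pad * span, bins + 1)


def fes_2d(traj: Trajectory, x: str, y: str, bins: int = 40,
           temperature: float = 300.0,
           equilibration_fraction: float = 0.0) -> FreeEnergySurface:
    """Project a trajectory onto two observables and return -kT ln P.

    Observables are any of q_w, q_c, or an energy component name.  The
    surface is in kT units (so ``temperature`` only labels the result).
    """
    xs = np.asarray(traj.observable(x), dtype=float)
    ys = np.asarray(traj.observable(y), dtype=float)
    skip = int(equilibration_fraction * len(xs))
    xs, ys = xs[skip:], ys[skip:]
    keep = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[keep], ys[keep]
    if len(xs) == 0:
        raise ValueError("no finite samples to histogram")
    xe = _edges(xs, bins)
    ye = _edges(ys, bins)
    counts, _, _ = np.histogram2d(xs, ys, bins=[xe, ye])
    with np.errstate(divide="ignore"):
        f = -np.log(counts / counts.sum())
    f[counts == 0] = np.nan
    f -= np.nanmin(f)
    return FreeEnergySurface(x, y, xe, ye, f, counts.astype(int),
                             temperature)


def fes_1d(samples: np.ndarray, bins: int = 40,
           coordinate: str = "q_w",
           temperature: float = 300.0) -> FreeEnergyProfile:
    """Unbiased 1D -kT ln P profile from scalar samples."""
    samples = np.asarray(samples, dtype=float)
    edges = _edges(samples, bins)
    counts, _ = np.histogram(samples, bins=edges)
    with np.errstate(divide="ignore"):
        f = -np.log(counts / counts.sum())
    f[counts == 0] = np.nan
    f -= np.nanmin(f)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FreeEnergyProfile(coordinate, centers, f, temperature)


def wham(windows: list[UmbrellaWindow], bins: int = 50,
         tol: float = 1e-8, max_iter: int = 100000,
         coordinate: str = "q_w") -> FreeEnergyProfile:
    """Weighted-histogram recombination of umbrella windows.

    Iterates the standard binned self-consistency equations

        P(b) ~ sum_k h_k(b) / sum_k N_k exp(f_k - beta w_k(b)),
        exp(-f_k) = sum_b P(b) exp(-beta w_k(b)),

    until the window free-energy shifts move by less than ``tol``
    (in kT).  All windows must share one temperature.
    """
    if not windows:
        raise ValueError("no umbrella windows supplied")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValueError(f"windows at mixed temperatures {sorted(temps)}")
    temperature = temps.pop()
    kT = KB * temperature
    data = [np.asarray(w.samples, dtype=float) for w in windows]
    if any(d is None or len(d) == 0 for d in data):
        raise ValueError("every window needs recorded samples")
    allq = np.concatenate(data)
    edges = _edges(allq, bins, pad=0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_k = np.array([len(d) for d in data], dtype=float)
    h_kb = np.stack([np.histogram(d, bins=edges)[0] for d in data]).astype(float)
    # bias energies at bin centers, in kT
    w_kb = np.stack([0.5 * w.k_bias * (centers - w.q0) ** 2 / kT
                     for w in windows])
    num = h_kb.sum(axis=0)
    f_k = np.zeros(len(windows))
    for _it in range(max_iter):
        denom = (n_k[:, None] * np.exp(f_k[:, None] - w_kb)).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, num / denom, 0.0)
        z = (p[None, :] * np.exp(-w_kb)).sum(axis=1)
        new_f = -np.log(np.maximum(z, 1e-300))
        new_f -= new_f[0]
        delta = np.max(np.abs(new_f - f_k))
        f_k = new_f
        if delta < tol:
            break
    else:
        warnings.warn(
            f"WHAM did not converge to {tol} in {max_iter} iterations "
            f"(last shift {delta:.2e}); windows may not overlap",
            stacklevel=2)
    with np.errstate(divide="ignore"):
        f = -np.log(np.where(p > 0, p, np.nan))
    f -= np.nanmin(f)
    return FreeEnergyProfile(coordinate, centers, f, temperature)


@dataclass
class Basin:
    location: float     # coordinate of the local minimum
    f_min: float        # profile value there (kT)
    depth: float        # height of the lowest confining barrier (kT)
    barrier: float | None  # barrier crest separating it from the next basin


def basin_report(profile: FreeEnergyProfile) -> list[Basin]:
    """Local minima of a 1D profile with their confining barriers.

    A basin's depth is the smaller of the two barrier rises around it;
    profile ends count as infinitely high walls, so a single-well
    profile reports one basin with no barrier.
    """
    mask = np.isfinite(profile.f)
    x = profile.centers[mask]
    f = profile.f[mask]
    if len(f) < 3:
        raise ValueError("profile too short for basin analysis")
    minima = [i for i in range(len(f))
              if (i == 0 or f[i] <= f[i - 1])
              and (i == len(f) - 1 or f[i] < f[i + 1])]
    # collapse flat runs
    basins = []
    for i in minima:
        if basins and i - basins[-1] == 1 and f[i] == f[basins[-1]]:
            continue
        basins.append(i)
    out = []
    for b_i, i in enumerate(basins):
        left = f[:i + 1]
        right = f[i:]
        rise_left = (left.max() - f[i]) if i > 0 else np.inf
        rise_right = (right.max() - f[i]) if i < len(f) - 1 else np.inf
        if len(basins) == 1:
            depth = max(f.max() - f[i], 0.0)
            crest = None
        else:
            depth = min(rise_left, rise_right)
            if b_i + 1 < len(basins):
                j = basins[b_i + 1]
                crest = float(f[i:j + 1].max())
            else:
                crest = None
        out.append(Basin(location=float(x[i]), f_min=float(f[i]),
                         depth=float(depth), barrier=crest))
    return out
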