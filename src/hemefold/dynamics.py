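"""Langevin dynamics, simulated annealing, and Q_w umbrella sampling.

The integrator is BAOAB-discretized Langevin dynamics in MD units
(nm, ps, amu, kJ/mol; kB = 0.00831 kJ/mol/K).  Annealing ramps the
thermostat linearly from ``t_start`` to ``t_end`` — the structure
prediction protocol — while umbrella sampling holds a fixed temperature
and adds a harmonic bias ``0.5 k (Q_w - q0)^2`` whose force is obtained
by chain-ruling the analytic Q_w gradient over all Calpha pairs.

Trajectories are reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .forcefield import CouplingSwitches, forces_and_energy
from .metrics import q_c, q_w, q_w_gradient
from .model_io import SystemState
from .params import KB, ParameterSet

__all__ = ["SimulationConfig", "UmbrellaWindow", "Trajectory",
           "LangevinIntegrator", "langevin_step", "anneal", "umbrella_run",
           "SimulationBlowupError"]


class SimulationBlowupError(RuntimeError):
    """Coordinates became non-finite during integration."""


@dataclass
class SimulationConfig:
    timestep: float = 0.005      # ps
    friction: float = 1.0        # 1/ps
    t_start: float = 800.0       # K
    t_end: float = 200.0         # K
    n_steps: int = 10000
    seed: int = 0
    record_every: int = 100
    #: flat-bottom tether on the heme centre of mass relative to the
    #: protein centre of mass: zero inside ``tether_radius``, harmonic
    #: (``tether_k``) outside.  This bounds the search volume — i.e.
    #: fixes an effective concentration — so that binding events are
    #: observable in short runs; it exerts no force on bound or nearby
    #: configurations.  Set ``tether_radius`` to None to disable.
    tether_radius: float | None = None   # nm
    tether_k: float = 50.0               # kJ/mol/nm^2

    def __post_init__(self):
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.t_start < self.t_end:
            raise ValueError("annealing requires t_start >= t_end")


@dataclass
class UmbrellaWindow:
    q0: float
    k_bias: float                 # kJ/mol
    temperature: float = 300.0    # K
    samples: np.ndarray | None = None      # recorded Q_w series
    energy_samples: np.ndarray | None = None  # total coupling energy series

    def __post_init__(self):
        if self.k_bias < 0:
            raise ValueError("k_bias must be >= 0")


@dataclass
class Trajectory:
    """Recorded frames of one run: observables plus raw coordinates."""
    steps: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    temperatures: np.ndarray = field(default_factory=lambda: np.empty(0))
    coordinates: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 3)))
    q_w: np.ndarray = field(default_factory=lambda: np.empty(0))
    q_c: np.ndarray = field(default_factory=lambda: np.empty(0))
    energies: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.steps)

    def observable(self, name: str) -> np.ndarray:
        """Fetch an observable series by name (q_w, q_c, or an energy
        component such as fe_cc / thioester / total)."""
        if name == "q_w":
            return self.q_w
        if name == "q_c":
            return self.q_c
        if name in self.energies:
            return self.energies[name]
        valid = ["q_w", "q_c"] + sorted(self.energies)
        raise KeyError(f"unknown observable {name!r}; valid: {valid}")

    def best_qw_frame(self) -> int:
        return int(np.argmax(self.q_w))

    def save(self, path) -> None:
        np.savez_compressed(
            path, steps=self.steps, temperatures=self.temperatures,
            coordinates=self.coordinates, q_w=self.q_w, q_c=self.q_c,
            energy_names=np.array(sorted(self.energies)),
            **{f"energy_{k}": v for k, v in self.energies.items()})

    @classmethod
    def load(cls, path) -> "Trajectory":
        with np.load(path, allow_pickle=False) as z:
            energies = {str(k): z[f"energy_{k}"] for k in z["energy_names"]}
            return cls(steps=z["steps"], temperatures=z["temperatures"],
                       coordinates=z["coordinates"], q_w=z["q_w"],
                       q_c=z["q_c"], energies=energies)


class LangevinIntegrator:
    """BAOAB Langevin integrator over a flat (n, 3) coordinate array.

    ``force_fn(x) -> (forces, aux)`` supplies forces; ``aux`` is passed
    through to the caller on request.  Velocities are initialised from
    the Maxwell-Boltzmann distribution at the starting temperature.
    """

    def __init__(self, force_fn, masses: np.ndarray, timestep: float,
                 friction: float, rng: np.random.Generator):
        self.force_fn = force_fn
        self.m = np.asarray(masses, dtype=float)[:, None]
        self.dt = float(timestep)
        self.gamma = float(friction)
        self.rng = rng
        self.c1 = np.exp(-self.gamma * self.dt)
        self._kick = 0.5 * self.dt / self.m

    def initialize_velocities(self, n: int, temperature: float) -> np.ndarray:
        if temperature <= 0:
            return np.zeros((n, 3))
        sigma = np.sqrt(KB * temperature / self.m)
        return sigma * self.rng.standard_normal((n, 3))

    def step(self, x, v, f, temperature: float):
        """One BAOAB step; returns (x, v, f, aux) at the new state."""
        v = v + self._kick * f
        x = x + 0.5 * self.dt * v
        if self.gamma > 0:
            noise = np.sqrt(KB * max(temperature, 0.0) / self.m
                            * (1.0 - self.c1 ** 2))
            v = self.c1 * v + noise * self.rng.standard_normal(x.shape)
        x = x + 0.5 * self.dt * v
        f, aux = self.force_fn(x)
        v = v + self._kick * f
        return x, v, f, aux

    def kinetic_energy(self, v) -> float:
        return float(0.5 * np.sum(self.m * v * v))


def langevin_step(state: SystemState, native: SystemState | None,
                  params: ParameterSet, config: SimulationConfig,
                  rng: np.random.Generator,
                  velocities: np.ndarray | None = None,
                  temperature: float | None = None):
    """Advance a :class:`SystemState` by one Langevin step (convenience
    wrapper over :class:`LangevinIntegrator`); returns velocities for
    chaining."""
    def force_fn(x):
        state.set_coords(x)
        return forces_and_energy(state, native, params)

    integ = LangevinIntegrator(force_fn, state.particle_masses(),
                               config.timestep, config.friction, rng)
    T = config.t_start if temperature is None else temperature
    x = state.get_coords()
    if velocities is None:
        velocities = integ.initialize_velocities(len(x), T)
    f, _ = force_fn(x)
    x, v, _, _ = integ.step(x, velocities, f, T)
    state.set_coords(x)
    return state, v


def _make_tether(state: SystemState, config: SimulationConfig):
    """Flat-bottom COM-COM restraint force closure, or None if disabled.

    A protocol-level restraint (not part of the model Hamiltonian): it
    only bounds how far the heme may wander from the protein.
    """
    if config.tether_radius is None or state.heme is None:
        return None
    masses = state.particle_masses()
    n_prot = state.n_particles - state.heme.n_atoms
    mp = masses[:n_prot, None]
    mh = masses[n_prot:, None]
    mp_tot = float(mp.sum())
    mh_tot = float(mh.sum())
    radius, k = config.tether_radius, config.tether_k

    def add_tether(x: np.ndarray, f: np.ndarray) -> None:
        com_p = (mp * x[:n_prot]).sum(axis=0) / mp_tot
        com_h = (mh * x[n_prot:]).sum(axis=0) / mh_tot
        d = com_h - com_p
        dist = float(np.linalg.norm(d))
        if dist <= radius:
            return
        pull = -k * (dist - radius) * d / dist
        f[n_prot:] += pull * (mh / mh_tot)
        f[:n_prot] -= pull * (mp / mp_tot)

    return add_tether


def _record(traj_lists, step, T, x, bd, state, native):
    qw = q_w(state.protein, native.protein)
    try:
        qc = q_c(state, native)
    except ValueError:
        qc = np.nan
    traj_lists["steps"].append(step)
    traj_lists["temperatures"].append(T)
    traj_lists["coordinates"].append(x.copy())
    traj_lists["q_w"].append(qw)
    traj_lists["q_c"].append(qc)
    for k, v in bd.as_dict().items():
        traj_lists["energies"].setdefault(k, []).append(v)


def _finish(traj_lists) -> Trajectory:
    return Trajectory(
        steps=np.array(traj_lists["steps"], dtype=int),
        temperatures=np.array(traj_lists["temperatures"]),
        coordinates=np.array(traj_lists["coordinates"]),
        q_w=np.array(traj_lists["q_w"]),
        q_c=np.array(traj_lists["q_c"]),
        energies={k: np.array(v)
                  for k, v in traj_lists["energies"].items()})


def anneal(state: SystemState, native: SystemState, params: ParameterSet,
           config: SimulationConfig,
           switches: CouplingSwitches | None = None) -> Trajectory:
    """Simulated-annealing prediction run.

    The thermostat temperature ramps linearly from ``t_start`` to
    ``t_end`` over ``n_steps``.  The caller provides a disordered start
    (extended protein, heme a few nm away); the final frame is the
    prediction and the best-Q_w frame is available from the trajectory.
    ``state`` is advanced in place and also returned inside the
    trajectory's last frame.
    """
    rng = np.random.default_rng(config.seed)
    lists = {"steps": [], "temperatures": [], "coordinates": [],
             "q_w": [], "q_c": [], "energies": {}}
    tether = _make_tether(state, config)

    def force_fn(x):
        state.set_coords(x)
        f, bd = forces_and_energy(state, native, params, switches=switches)
        if tether is not None:
            tether(x, f)
        return f, bd

    x = state.get_coords()
    f, bd = force_fn(x)
    _record(lists, 0, config.t_start, x, bd, state, native)
    if config.n_steps == 0:
        return _finish(lists)

    integ = LangevinIntegrator(force_fn, state.particle_masses(),
                               config.timestep, config.friction, rng)
    v = integ.initialize_velocities(len(x), config.t_start)
    temps = np.linspace(config.t_start, config.t_end, config.n_steps)
    for i, T in enumerate(temps, start=1):
        x, v, f, bd = integ.step(x, v, f, T)
        if i % config.record_every == 0 or i == config.n_steps:
            if not np.isfinite(x).all():
                raise SimulationBlowupError(
                    f"non-finite coordinates at step {i} (T={T:.1f} K); "
                    "reduce the timestep or soften the starting structure")
            state.set_coords(x)
            _record(lists, i, T, x, bd, state, native)
    return _finish(lists)


def umbrella_run(state: SystemState, native: SystemState,
                 params: ParameterSet, windows: list[UmbrellaWindow],
                 config: SimulationConfig,
                 switches: CouplingSwitches | None = None,
                 equilibration_fraction: float = 0.2
                 ) -> list[UmbrellaWindow]:
    """Run one biased trajectory per umbrella window.

    Each window samples at its own fixed temperature with the bias
    ``0.5 k_bias (Q_w - q0)^2`` added to the Hamiltonian; every window
    starts from a copy of ``state``.  Returns the windows with their
    recorded Q_w series (equilibration discarded).  Neighbouring
    windows whose histograms share less than 10% overlapping mass
    trigger a warning.
    """
    n_res = state.protein.n_residues
    ref_ca = native.protein.ca
    results = []
    for w_i, window in enumerate(windows):
        run_state = state.copy()
        rng = np.random.default_rng((config.seed, w_i))
        tether = _make_tether(run_state, config)

        def force_fn(x, _window=window, _tether=tether):
            run_state.set_coords(x)
            f, bd = forces_and_energy(run_state, native, params,
                                      switches=switches)
            qw, dqw = q_w_gradient(run_state.protein.ca, ref_ca)
            f[:n_res] -= _window.k_bias * (qw - _window.q0) * dqw
            if _tether is not None:
                _tether(x, f)
            return f, (bd, qw)

        integ = LangevinIntegrator(force_fn, run_state.particle_masses(),
                                   config.timestep, config.friction, rng)
        x = run_state.get_coords()
        f, (bd, qw) = force_fn(x)
        v = integ.initialize_velocities(len(x), window.temperature)
        qws, couplings = [], []
        for i in range(1, config.n_steps + 1):
            x, v, f, (bd, qw) = integ.step(x, v, f, window.temperature)
            if i % config.record_every == 0:
                if not np.isfinite(x).all():
                    raise SimulationBlowupError(
                        f"window q0={window.q0}: non-finite coordinates "
                        f"at step {i}")
                qws.append(qw)
                couplings.append(bd.total - bd.protein_standin
                                 - bd.heme_internal)
        skip = int(equilibration_fraction * len(qws))
        window.samples = np.array(qws[skip:])
        window.energy_samples = np.array(couplings[skip:])
        results.append(window)

    for a, b in zip(results[:-1], results[1:]):
        if a.samples is None or b.samples is None:
            continue
        lo = min(a.samples.min(), b.samples.min())
        hi = max(a.samples.max(), b.samples.max())
        bins = np.linspace(lo, hi, 40)
        ha, _ = np.histogram(a.samples, bins=bins, density=True)
        hb, _ = np.histogram(b.samples, bins=bins, density=True)
        width = bins[1] - bins[0]
        overlap = np.minimum(ha, hb).sum() * width
        if overlap < 0.10:
            warnings.warn(
                f"umbrella windows q0={a.q0:.2f} and q0={b.q0:.2f} share "
                f"only {overlap:.1%} histogram mass; add windows or "
                "soften the bias", stacklevel=2)
    return results
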