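"""Classical and thermostatted ring-polymer MD engines.

A single BAOAB-split integrator drives both flavors: bead positions are
propagated exactly in the free-ring-polymer normal-mode basis (A step),
physical forces act per bead (B step), and a PILE thermostat acts per normal
mode (O step).  With P = 1 the normal-mode transform is the identity and the
engine reduces bit-for-bit to classical Langevin (or NVE) velocity-Verlet.

Bead-temperature convention: ring-polymer springs use ω_P = P·k_B·T/ħ and
bead momenta are Maxwell-distributed at P·T, i.e. the extended system is
sampled at temperature P·T.  Centroid positions/velocities are exported for
dynamical observables; bead-resolved storage is optional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .system import Configuration, GhostMDError, wrap_positions
from .units import ATOMIC_MASSES, HBAR, KB, MASS_EV

logger = logging.getLogger(__name__)


@dataclass
class MDOptions:
    """Integration options shared by classical and ring-polymer runs."""

    dt: float = 0.5                 # fs
    steps: int = 1000
    temperature: float = 300.0      # K
    thermostat: str = "langevin"    # 'none' | 'langevin'
    friction: float = 0.05          # fs⁻¹, centroid/classical friction
    pile_lambda: float = 0.5        # internal-mode friction scale γ_k = 2λω_k
    seed: int = 0
    stride: int = 10                # frame storage interval
    store_velocities: bool = True

    def validate(self) -> None:
        if self.thermostat not in ("none", "langevin"):
            raise GhostMDError(f"unknown thermostat {self.thermostat!r}")
        if self.dt <= 0 or self.steps < 0:
            raise GhostMDError("dt must be > 0 and steps >= 0")


@dataclass
class RingPolymerState:
    """P replicas of a configuration with isotope masses and velocities."""

    positions: np.ndarray    # (P, N, 3) Å
    velocities: np.ndarray   # (P, N, 3) Å/fs
    masses: np.ndarray       # (N,) amu
    temperature: float       # K (physical)
    species: np.ndarray
    cell: np.ndarray
    molecule_index: np.ndarray

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def copy(self) -> "RingPolymerState":
        return RingPolymerState(self.positions.copy(), self.velocities.copy(),
                                self.masses.copy(), self.temperature,
                                self.species.copy(), self.cell.copy(),
                                self.molecule_index.copy())

    def config(self) -> Configuration:
        return Configuration(self.species, wrap_positions(self.centroid, self.cell),
                             self.cell, self.molecule_index)


@dataclass
class Trajectory:
    """Stored frames of one run (centroid view; beads optional)."""

    times: np.ndarray                 # (F,) fs
    positions: np.ndarray             # (F, N, 3) Å (centroid for P > 1)
    cell: np.ndarray
    species: np.ndarray
    molecule_index: np.ndarray
    velocities: np.ndarray | None = None        # (F, N, 3) Å/fs
    bead_positions: np.ndarray | None = None    # (F, P, N, 3)
    potential_energy: np.ndarray | None = None  # (F,) eV (bead average)
    total_energy: np.ndarray | None = None      # (F,) eV, conserved qty diagnostics
    metadata: dict = field(default_factory=dict)
    final_state: RingPolymerState | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dt_frame(self) -> float:
        if self.n_frames < 2:
            raise GhostMDError("need >= 2 frames for a frame interval")
        return float(self.times[1] - self.times[0])

    def frame_config(self, i: int) -> Configuration:
        return Configuration(self.species,
                             wrap_positions(self.positions[i], self.cell),
                             self.cell, self.molecule_index)

    def to_extxyz(self, path) -> None:
        from .io import write_trajectory_extxyz
        write_trajectory_extxyz(path, self)

    @classmethod
    def from_extxyz(cls, path) -> "Trajectory":
        from .io import read_trajectory_extxyz
        return read_trajectory_extxyz(path)

    def to_hdf5(self, path) -> None:
        from .io import write_trajectory_hdf5
        write_trajectory_hdf5(path, self)

    @classmethod
    def from_hdf5(cls, path) -> "Trajectory":
        from .io import read_trajectory_hdf5
        return read_trajectory_hdf5(path)


# ---------------------------------------------------------------------------
# normal modes of the free ring polymer
# ---------------------------------------------------------------------------

def normal_mode_matrix(P: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal transform C (q = C·x over the bead axis) and |mode| index k.

    Rows: 0 → centroid; pairs (cos, sin) for k = 1..; row P/2 (P even) is the
    alternating mode.  Returns (C (P, P), k_of_row (P,)).
    """
    C = np.zeros((P, P))
    k_of_row = np.zeros(P, dtype=int)
    b = np.arange(P)
    C[0] = 1.0 / np.sqrt(P)
    row = 1
    for k in range(1, (P + 1) // 2):
        C[row] = np.sqrt(2.0 / P) * np.cos(2 * np.pi * k * b / P)
        k_of_row[row] = k
        row += 1
        C[row] = np.sqrt(2.0 / P) * np.sin(2 * np.pi * k * b / P)
        k_of_row[row] = k
        row += 1
    if P % 2 == 0:
        C[row] = (1.0 / np.sqrt(P)) * (-1.0) ** b
        k_of_row[row] = P // 2
    return C, k_of_row


def ring_frequencies(P: int, temperature: float) -> np.ndarray:
    """Free-ring-polymer normal-mode angular frequencies ω_k (fs⁻¹) per row."""
    omega_P = P * KB * temperature / HBAR
    _, k_of_row = normal_mode_matrix(P)
    return 2.0 * omega_P * np.sin(np.pi * k_of_row / P)


def init_ring_polymer(config: Configuration, P: int, temperature: float,
                      seed: int = 0,
                      velocities: np.ndarray | None = None) -> RingPolymerState:
    """Thermal free-ring-polymer initialization around a configuration.

    Internal modes get Gaussian displacements with the free-polymer variance
    k_B·P·T/(m·ω_k²); momenta are Maxwell at P·T unless given explicitly.
    P = 1 returns the configuration unchanged (classical state).
    """
    if P < 1:
        raise GhostMDError("P must be >= 1")
    masses = config.masses
    N = config.n_atoms
    rng = np.random.default_rng(seed)
    C, _ = normal_mode_matrix(P)
    omegas = ring_frequencies(P, temperature)
    q = np.zeros((P, N, 3))
    q[0] = np.sqrt(P) * config.positions      # centroid row: q0 = √P · x̄
    kT_P = KB * P * temperature
    for r in range(1, P):
        sigma = np.sqrt(kT_P / (masses * MASS_EV * omegas[r] ** 2))
        q[r] = sigma[:, None] * rng.standard_normal((N, 3))
    pos = np.einsum("rb,rnc->bnc", C, q)
    if velocities is None:
        sig_v = np.sqrt(kT_P / (masses * MASS_EV))
        vel = sig_v[None, :, None] * rng.standard_normal((P, N, 3))
    else:
        vel = np.broadcast_to(np.asarray(velocities, float), (P, N, 3)).copy()
    return RingPolymerState(pos, vel, masses, temperature, config.species,
                            config.cell, config.molecule_index)


def spring_potential_energy(state: RingPolymerState) -> float:
    """Total ring-polymer spring energy Σ_i Σ_b ½ m_i ω_P² |r_{i,b+1}−r_{i,b}|²."""
    P = state.n_beads
    if P == 1:
        return 0.0
    omega_P = P * KB * state.temperature / HBAR
    d = state.positions - np.roll(state.positions, -1, axis=0)
    return float(0.5 * MASS_EV * omega_P ** 2 *
                 np.sum(state.masses[None, :, None] * d * d))


# ---------------------------------------------------------------------------
# the integrator
# ---------------------------------------------------------------------------

def _check_timestep(potential, opts: MDOptions) -> None:
    wmax = getattr(potential, "max_frequency", None)
    if wmax:
        period = 2 * np.pi / wmax
        if opts.dt > period / 20.0:
            raise GhostMDError(
                f"dt={opts.dt} fs does not resolve the fastest period "
                f"({period:.2f} fs); need >= 20 steps/period")


def _integrate(state: RingPolymerState, potential, opts: MDOptions,
               store_beads: bool = False, record_conserved: bool = False) -> Trajectory:
    opts.validate()
    _check_timestep(potential, opts)
    P, N = state.n_beads, state.n_atoms
    dt = opts.dt
    m3 = (state.masses * MASS_EV)[None, :, None]     # (1, N, 1) eV·fs²/Å²
    rng = np.random.default_rng(opts.seed)

    C, _ = normal_mode_matrix(P)
    omegas = ring_frequencies(P, state.temperature)
    half = 0.5 * dt
    cos_h = np.cos(omegas * half)
    sinc_h = np.array([np.sin(w * half) / w if w > 0 else half for w in omegas])
    wsin_h = omegas * np.sin(omegas * half)

    langevin = opts.thermostat == "langevin"
    if langevin:
        gammas = 2.0 * opts.pile_lambda * omegas
        gammas[0] = opts.friction
        c1 = np.exp(-gammas * dt)
        c2 = np.sqrt(1.0 - c1 * c1)
        kT_P = KB * P * state.temperature
        sig_v = np.sqrt(kT_P / (state.masses * MASS_EV))    # (N,)

    x = state.positions.copy()
    v = state.velocities.copy()
    E, F = potential.energy_forces(x)
    if not np.all(np.isfinite(F)):
        raise GhostMDError("non-finite forces at step 0")

    n_store = opts.steps // opts.stride + 1
    times = np.empty(n_store)
    pos_out = np.empty((n_store, N, 3))
    vel_out = np.empty((n_store, N, 3)) if opts.store_velocities else None
    bead_out = np.empty((n_store, P, N, 3)) if store_beads else None
    epot_out = np.empty(n_store)
    etot_out = np.empty(n_store) if record_conserved else None

    def _record(idx, step):
        times[idx] = step * dt
        pos_out[idx] = x.mean(axis=0)
        if vel_out is not None:
            vel_out[idx] = v.mean(axis=0)
        if bead_out is not None:
            bead_out[idx] = x
        epot_out[idx] = np.mean(E)
        if etot_out is not None:
            ke = 0.5 * np.sum(m3 * v * v)
            spring = spring_potential_energy(
                RingPolymerState(x, v, state.masses, state.temperature,
                                 state.species, state.cell,
                                 state.molecule_index))
            etot_out[idx] = ke + np.sum(E) + spring

    _record(0, 0)
    stored = 1
    for step in range(1, opts.steps + 1):
        v += half * F / m3                               # B
        q = np.einsum("rb,bnc->rnc", C, x)               # to normal modes
        u = np.einsum("rb,bnc->rnc", C, v)
        # A (dt/2): exact free-ring-polymer evolution
        q_new = cos_h[:, None, None] * q + sinc_h[:, None, None] * u
        u_new = -wsin_h[:, None, None] * q + cos_h[:, None, None] * u
        q, u = q_new, u_new
        if langevin:                                     # O (full dt)
            noise = rng.standard_normal((P, N, 3))
            u = c1[:, None, None] * u + \
                (c2[:, None, None] * sig_v[None, :, None]) * noise
        # A (dt/2)
        q_new = cos_h[:, None, None] * q + sinc_h[:, None, None] * u
        u_new = -wsin_h[:, None, None] * q + cos_h[:, None, None] * u
        q, u = q_new, u_new
        x = np.einsum("rb,rnc->bnc", C, q)               # back to beads
        v = np.einsum("rb,rnc->bnc", C, u)
        E, F = potential.energy_forces(x)
        if not np.all(np.isfinite(F)):
            raise GhostMDError(f"non-finite forces at step {step}; "
                               f"centroid dump: {x.mean(axis=0)!r}")
        v += half * F / m3                               # B
        if step % opts.stride == 0:
            _record(stored, step)
            stored += 1

    final = RingPolymerState(x, v, state.masses, state.temperature,
                             state.species, state.cell, state.molecule_index)
    meta = dict(dt=dt, stride=opts.stride, temperature=state.temperature,
                P=P, seed=opts.seed, thermostat=opts.thermostat,
                friction=opts.friction,
                masses=state.masses.copy())
    return Trajectory(times[:stored], pos_out[:stored], state.cell,
                      state.species, state.molecule_index,
                      velocities=vel_out[:stored] if vel_out is not None else None,
                      bead_positions=bead_out[:stored] if bead_out is not None else None,
                      potential_energy=epot_out[:stored],
                      total_energy=etot_out[:stored] if etot_out is not None else None,
                      metadata=meta, final_state=final)


def run_md(config_or_state, potential, opts: MDOptions,
           record_conserved: bool = False) -> Trajectory:
    """Classical MD (velocity-Verlet / BAOAB Langevin), deterministic per seed.

    Accepts a Configuration (velocities drawn Maxwell at T from the seed) or a
    P = 1 RingPolymerState (for restarts with explicit velocities).
    """
    if isinstance(config_or_state, RingPolymerState):
        state = config_or_state
        if state.n_beads != 1:
            raise GhostMDError("run_md requires a single-bead state")
    else:
        state = init_ring_polymer(config_or_state, 1, opts.temperature,
                                  seed=opts.seed)
    return _integrate(state, potential, opts, record_conserved=record_conserved)


def run_trpmd(state: RingPolymerState, potential, opts: MDOptions,
              store_beads: bool = False,
              record_conserved: bool = False) -> Trajectory:
    """Thermostatted ring-polymer MD (PILE internal friction γ_k = 2λω_k).

    With thermostat='langevin' and friction=0 this is production TRPMD
    (thermostat-free centroid); a positive centroid friction gives the global
    PILE variant suitable for equilibration.  thermostat='none' propagates
    the bare ring-polymer Hamiltonian (exact free-polymer A step).
    """
    return _integrate(state, potential, opts, store_beads=store_beads,
                      record_conserved=record_conserved)


# ---------------------------------------------------------------------------
# electron-injection protocol
# ---------------------------------------------------------------------------

@dataclass
class InjectionOptions:
    equil_steps: int = 400
    production_steps: int = 1200
    n_replicas: int = 10
    seeds: list[int] | None = None
    dt: float = 0.5
    temperature: float = 300.0
    friction: float = 0.05
    stride: int = 20
    radius_threshold: float = 2.55      # Å, maximin void radius for "localized"
    grid_spacing: float = 0.45          # Å, void-finder grid
    consecutive: int = 2                # frames above threshold to call an event


def injection_run(config: Configuration, neat_potential, electron_potential,
                  opts: InjectionOptions):
    """Simulate solute injection: equilibrate neat, switch potentials at t=0.

    Per replica: Langevin equilibration under the neat potential, then the
    potential is switched (the "injection") and production frames are
    recorded.  The event log marks the first time the largest maximin void
    radius stays above ``radius_threshold`` for ``consecutive`` stored frames.

    Returns (trajectories, events); each event is a dict with keys
    replica / seed / event_time (fs or None) / radius_series.
    """
    from .analysis import void_center

    na, nb = getattr(neat_potential, "n_atoms", None), \
        getattr(electron_potential, "n_atoms", None)
    if na is not None and nb is not None and na != nb:
        raise GhostMDError("neat and electron potentials differ in system size "
                           "(potentials are concentration-specific)")
    seeds = opts.seeds or list(range(opts.n_replicas))
    trajectories, events = [], []
    for rep, seed in enumerate(seeds):
        eq = run_md(config, neat_potential,
                    MDOptions(dt=opts.dt, steps=opts.equil_steps,
                              temperature=opts.temperature,
                              thermostat="langevin", friction=opts.friction,
                              seed=seed, stride=max(opts.equil_steps, 1),
                              store_velocities=True))
        state = eq.final_state
        prod = _integrate(state, electron_potential,
                          MDOptions(dt=opts.dt, steps=opts.production_steps,
                                    temperature=opts.temperature,
                                    thermostat="langevin",
                                    friction=opts.friction, seed=seed + 7919,
                                    stride=opts.stride, store_velocities=True))
        radii = np.empty(prod.n_frames)
        for i in range(prod.n_frames):
            rec = void_center(prod.frame_config(i), opts.grid_spacing,
                              radius_threshold=0.0)
            radii[i] = rec.maximin_radii[0] if len(rec.maximin_radii) else 0.0
        above = radii >= opts.radius_threshold
        event_time = None
        run = 0
        for i, a in enumerate(above):
            run = run + 1 if a else 0
            if run >= opts.consecutive:
                event_time = float(prod.times[i - opts.consecutive + 1])
                break
        trajectories.append(prod)
        events.append(dict(replica=rep, seed=seed, event_time=event_time,
                           radius_series=radii))
        logger.info("injection replica %d (seed %d): event at %s",
                    rep, seed, event_time)
    return trajectories, events
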