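"""Synthetic reference system: a flexible polar toy fluid plus one ghost particle.

This module plays the role that an expensive correlated-electronic-structure
code plays in production work: it produces labeled configurations (energy +
per-atom forces) for training the machine-learning potential.  The fluid is
a minimal flexible 3-site water surrogate — harmonic OH bonds and HOH angle,
Lennard-Jones between oxygens, shifted-force Coulomb between intermolecular
sites.  The "electron" is a single ghost particle coupled to the nuclei by
a Gaussian attraction to H sites and a Gaussian repulsion from O sites; for
every configuration the ghost is relaxed to a local minimum of its coupling
energy, mimicking an adiabatically-following quasiparticle.  Because the
ghost sits at a stationary point, nuclear forces at fixed ghost equal total
derivatives (Hellmann–Feynman), so the labeled samples never reference the
ghost coordinates — its presence lives purely in the nuclear correlations.

Default parameters are frozen so that the relaxed ghost carves a cavity
lined by 4–5 H sites, with the signatures studied downstream (H shell closer
than O shell, red-shifted shell stretch band, H/D fractionation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .system import Configuration, GhostMDError, minimum_image, wrap_positions
from .units import COULOMB

logger = logging.getLogger(__name__)

HARD_FLOOR = 0.3  # Å; intermolecular distances below this abort the evaluation


@dataclass
class ToyModelParams:
    """Parameters of the toy fluid and its ghost coupling.

    Energies in eV, lengths in Å, angles in rad, charges in e.
    """

    k_bond: float = 25.0          # OH harmonic bond constant, eV/Å²
    r0: float = 0.9572            # OH equilibrium length, Å
    k_angle: float = 2.4          # HOH harmonic angle constant, eV/rad²
    theta0: float = 1.82421813    # HOH equilibrium angle, rad (104.52°)
    lj_epsilon: float = 0.025     # O–O Lennard-Jones well depth, eV
    lj_sigma: float = 3.1507      # O–O Lennard-Jones size, Å
    q_O: float = -0.834           # site charge on O, e
    q_H: float = 0.417            # site charge on H/D, e
    r_cut: float = 4.5            # shifted-force cutoff for LJ and Coulomb, Å
    ghost_A_H: float = 1.0        # ghost–H Gaussian well depth, eV (>0 attractive)
    ghost_sigma_H: float = 1.8    # ghost–H Gaussian width, Å
    ghost_A_O: float = 18.0       # ghost–O Gaussian repulsion height, eV (≥0)
    ghost_sigma_O: float = 1.65   # ghost–O Gaussian width, Å

    def validate(self) -> None:
        if self.ghost_A_H <= 0:
            raise GhostMDError("ghost_A_H must be > 0 (attractive to H)")
        if self.ghost_A_O < 0:
            raise GhostMDError("ghost_A_O must be >= 0")
        if self.r_cut <= 0:
            raise GhostMDError("r_cut must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ToyModelParams":
        return cls(**d)


@dataclass
class GhostState:
    """Relaxed ghost particle for one configuration."""

    position: np.ndarray   # (3,) Å, wrapped into the cell
    energy: float          # ghost-coupling energy at the minimum, eV
    converged: bool
    grad_norm: float = 0.0


@dataclass
class LabeledSample:
    """A configuration with its reference energy and nuclear forces."""

    configuration: Configuration
    energy: float              # eV
    forces: np.ndarray         # (N, 3) eV/Å
    has_ghost: bool


class Dataset:
    """A homogeneous collection of labeled samples (all neat or all ghost)."""

    def __init__(self, samples: list[LabeledSample], has_ghost: bool,
                 metadata: dict | None = None,
                 frame_labels: list[str] | None = None):
        for s in samples:
            if s.has_ghost != has_ghost:
                raise GhostMDError("dataset must be homogeneous in has_ghost")
        self.samples = samples
        self.has_ghost = has_ghost
        self.metadata = metadata or {}
        self.frame_labels = frame_labels

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, i: int) -> LabeledSample:
        return self.samples[i]

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.samples])

    @property
    def forces(self) -> np.ndarray:
        return np.stack([s.forces for s in self.samples])

    @property
    def configurations(self) -> list[Configuration]:
        return [s.configuration for s in self.samples]

    def subset(self, indices) -> "Dataset":
        labels = ([self.frame_labels[i] for i in indices]
                  if self.frame_labels is not None else None)
        return Dataset([self.samples[i] for i in indices], self.has_ghost,
                       dict(self.metadata), labels)

    @classmethod
    def concat(cls, parts: list["Dataset"],
               labels: list[str] | None = None) -> "Dataset":
        """Merge datasets (same has_ghost); optional per-part frame labels.

        Mixed training sets — cavity-state frames from adiabatic-ghost
        dynamics plus homogeneous frames from neat dynamics, all labeled on
        the same reference surface — are what keeps the learned potential
        honest outside the cavity basin.
        """
        if not parts:
            raise GhostMDError("nothing to concatenate")
        has_ghost = parts[0].has_ghost
        samples, frame_labels = [], []
        for i, part in enumerate(parts):
            if part.has_ghost != has_ghost:
                raise GhostMDError("cannot mix ghost and neat labels")
            samples.extend(part.samples)
            lab = labels[i] if labels else (part.frame_labels or ["all"])[0]
            frame_labels.extend([lab] * len(part))
        meta = dict(parts[0].metadata)
        meta["mixture"] = [len(p) for p in parts]
        return cls(samples, has_ghost, meta, frame_labels)

    # I/O lives in ghostmd.io; thin delegating wrappers keep one import direction.
    def to_extxyz(self, path) -> None:
        from .io import write_dataset_extxyz
        write_dataset_extxyz(path, self)

    @classmethod
    def from_extxyz(cls, path) -> "Dataset":
        from .io import read_dataset_extxyz
        return read_dataset_extxyz(path)

    def to_hdf5(self, path) -> None:
        from .io import write_dataset_hdf5
        write_dataset_hdf5(path, self)

    @classmethod
    def from_hdf5(cls, path) -> "Dataset":
        from .io import read_dataset_hdf5
        return read_dataset_hdf5(path)


# ---------------------------------------------------------------------------
# topology helpers
# ---------------------------------------------------------------------------

def molecular_topology(species: np.ndarray, molecule_index: np.ndarray):
    """Return (o_idx (M,), h_idx (M,2)) atom indices per molecule."""
    from .units import ELEMENT_OF
    n_mol = int(molecule_index.max()) + 1
    o_idx = np.empty(n_mol, dtype=int)
    h_idx = np.empty((n_mol, 2), dtype=int)
    for m in range(n_mol):
        atoms = np.flatnonzero(molecule_index == m)
        elems = [ELEMENT_OF[species[a]] for a in atoms]
        o = [a for a, e in zip(atoms, elems) if e == "O"]
        h = [a for a, e in zip(atoms, elems) if e == "H"]
        if len(o) != 1 or len(h) != 2:
            raise GhostMDError(f"molecule {m} must contain 1 O and 2 H/D sites")
        o_idx[m] = o[0]
        h_idx[m] = h
    return o_idx, h_idx


def _intermolecular_pairs(molecule_index: np.ndarray):
    """All unordered intermolecular atom pairs (i < j)."""
    n = len(molecule_index)
    ii, jj = np.triu_indices(n, k=1)
    mask = molecule_index[ii] != molecule_index[jj]
    return ii[mask], jj[mask]


# ---------------------------------------------------------------------------
# batched energy/forces core
# ---------------------------------------------------------------------------

class _Topology:
    """Precomputed index arrays for a fixed composition."""

    def __init__(self, config: Configuration, params: ToyModelParams):
        config.validate(max_cutoff=params.r_cut)
        self.species = config.species
        self.cell = config.cell
        self.molecule_index = config.molecule_index
        self.o_idx, self.h_idx = molecular_topology(config.species,
                                                    config.molecule_index)
        self.pi, self.pj = _intermolecular_pairs(config.molecule_index)
        elem = config.elements
        self.is_h = elem == "H"
        self.is_o = elem == "O"
        charges = np.where(self.is_o, params.q_O, params.q_H)
        self.qq = charges[self.pi] * charges[self.pj]
        self.oo_pair = self.is_o[self.pi] & self.is_o[self.pj]
        self.n_atoms = config.n_atoms


def _scatter_pair_forces(forces, idx_i, idx_j, fvec):
    """forces[..., idx_i, :] += fvec; forces[..., idx_j, :] -= fvec (batched)."""
    B, N = forces.shape[0], forces.shape[1]
    off = (np.arange(B)[:, None] * N)
    fi = (off + idx_i[None, :]).ravel()
    fj = (off + idx_j[None, :]).ravel()
    flat = forces.reshape(B * N, 3)
    for c in range(3):
        w = fvec[..., c].ravel()
        flat[:, c] += np.bincount(fi, weights=w, minlength=B * N)
        flat[:, c] -= np.bincount(fj, weights=w, minlength=B * N)


def _toy_ef_batch(pos: np.ndarray, topo: _Topology, params: ToyModelParams,
                  ghost_pos: np.ndarray | None = None):
    """Energy and forces for a batch of replicas sharing one topology.

    pos: (B, N, 3); ghost_pos: (B, 3) or None.
    Returns (E (B,), F (B, N, 3)).  Ghost coupling (if given) is evaluated at
    the provided ghost positions; forces on the ghost itself are NOT included
    in F (the adiabatic protocol keeps the ghost at a stationary point).
    """
    cell = topo.cell
    B, N = pos.shape[0], pos.shape[1]
    E = np.zeros(B)
    F = np.zeros((B, N, 3))

    # --- intramolecular: bonds ---------------------------------------
    o = topo.o_idx
    h = topo.h_idx
    d_oh = minimum_image(pos[:, h, :] - pos[:, o, :][:, :, None, :], cell)  # (B,M,2,3)
    r_oh = np.linalg.norm(d_oh, axis=-1)                                    # (B,M,2)
    dr = r_oh - params.r0
    E += 0.5 * params.k_bond * np.sum(dr * dr, axis=(1, 2))
    # force on H = -k dr * unit(d_oh); on O the opposite
    f_h = -params.k_bond * (dr / r_oh)[..., None] * d_oh                    # (B,M,2,3)
    _scatter_pair_forces(F, h.ravel(), np.repeat(o, 2),
                         f_h.reshape(B, -1, 3))

    # --- intramolecular: angles --------------------------------------
    u1 = d_oh[:, :, 0, :]
    u2 = d_oh[:, :, 1, :]
    r1 = r_oh[:, :, 0]
    r2 = r_oh[:, :, 1]
    cos_t = np.sum(u1 * u2, axis=-1) / (r1 * r2)
    cos_t = np.clip(cos_t, -1.0 + 1e-12, 1.0 - 1e-12)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(1.0 - cos_t * cos_t)
    dth = theta - params.theta0
    E += 0.5 * params.k_angle * np.sum(dth * dth, axis=1)
    # dθ/du1 = -(u2/(r1 r2) - cosθ u1/r1²)/sinθ
    pref = (params.k_angle * dth / sin_t)[..., None]
    dcos_du1 = u2 / (r1 * r2)[..., None] - cos_t[..., None] * u1 / (r1 * r1)[..., None]
    dcos_du2 = u1 / (r1 * r2)[..., None] - cos_t[..., None] * u2 / (r2 * r2)[..., None]
    # ∂θ/∂u = -(∂cosθ/∂u)/sinθ, so force on H1 = -k dθ ∂θ/∂u1 = pref·dcos_du1
    f_h1 = pref * dcos_du1
    f_h2 = pref * dcos_du2
    _scatter_pair_forces(F, h[:, 0], o, f_h1)
    _scatter_pair_forces(F, h[:, 1], o, f_h2)

    # --- intermolecular pairs ----------------------------------------
    pi, pj = topo.pi, topo.pj
    disp = minimum_image(pos[:, pi, :] - pos[:, pj, :], cell)               # (B,P,3)
    r = np.linalg.norm(disp, axis=-1)
    if np.any(r < HARD_FLOOR):
        raise GhostMDError(
            f"intermolecular distance below hard floor {HARD_FLOOR} Å "
            f"(min {r.min():.3f} Å)")
    rc = params.r_cut
    within = r < rc
    rinv = np.where(within, 1.0 / r, 0.0)

    # shifted-force Coulomb: V = qqk (1/r - 1/rc + (r-rc)/rc²)
    k = COULOMB
    e_c = topo.qq * k * (rinv - 1.0 / rc + (r - rc) / rc**2)
    fmag_c = topo.qq * k * (rinv * rinv - 1.0 / rc**2)   # = -dV/dr

    # shifted-force LJ on O–O pairs
    sr6 = np.where(within & topo.oo_pair, (params.lj_sigma * rinv) ** 6, 0.0)
    v_lj = 4.0 * params.lj_epsilon * (sr6 * sr6 - sr6)
    dv_lj = 4.0 * params.lj_epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) * rinv
    src6 = (params.lj_sigma / rc) ** 6
    v_lj_rc = 4.0 * params.lj_epsilon * (src6 * src6 - src6)
    dv_lj_rc = 4.0 * params.lj_epsilon * (-12.0 * src6 * src6 + 6.0 * src6) / rc
    e_lj = np.where(topo.oo_pair, v_lj - v_lj_rc - (r - rc) * dv_lj_rc, 0.0)
    fmag_lj = np.where(topo.oo_pair, -(dv_lj - dv_lj_rc), 0.0)

    e_pair = np.where(within, e_c + e_lj, 0.0)
    fmag = np.where(within, fmag_c + fmag_lj, 0.0)
    E += e_pair.sum(axis=1)
    fvec = (fmag * rinv)[..., None] * disp
    _scatter_pair_forces(F, pi, pj, fvec)

    # --- ghost coupling ----------------------------------------------
    if ghost_pos is not None:
        e_g, f_nuc, _ = _ghost_coupling(pos, ghost_pos, topo, params)
        E += e_g
        F += f_nuc
    return E, F


def _ghost_radial(r: np.ndarray, A: float, sigma: float, rc: float):
    """Smoothly truncated Gaussian u(r)=A·exp(−r²/2σ²)·f_c(r) and u', u''.

    The cosine cutoff f_c at rc (half the smallest box length) keeps the
    coupling C¹ across the minimum-image shell, so the ghost landscape has
    true stationary points instead of kinks.
    """
    inside = r < rc
    G = np.where(inside, np.exp(-r * r / (2 * sigma * sigma)), 0.0)
    x = np.pi * r / rc
    f = np.where(inside, 0.5 * (np.cos(x) + 1.0), 0.0)
    fp = np.where(inside, -0.5 * np.pi / rc * np.sin(x), 0.0)
    fpp = np.where(inside, -0.5 * (np.pi / rc) ** 2 * np.cos(x), 0.0)
    Gp = -(r / sigma**2) * G
    Gpp = G * (r * r / sigma**4 - 1.0 / sigma**2)
    u = A * G * f
    up = A * (Gp * f + G * fp)
    upp = A * (Gpp * f + 2.0 * Gp * fp + G * fpp)
    return u, up, upp


def _ghost_terms(topo: _Topology, params: ToyModelParams):
    rc = 0.5 * float(np.min(topo.cell))
    return ((-1.0, params.ghost_A_H, params.ghost_sigma_H, topo.is_h, rc),
            (+1.0, params.ghost_A_O, params.ghost_sigma_O, topo.is_o, rc))


def _ghost_coupling(pos, ghost_pos, topo: _Topology, params: ToyModelParams):
    """Ghost-coupling energy, nuclear forces, and gradient wrt ghost position.

    pos: (B, N, 3); ghost_pos: (B, 3).
    Returns (E (B,), F_nuc (B, N, 3), g_ghost (B, 3)).
    """
    cell = topo.cell
    d = minimum_image(pos - ghost_pos[:, None, :], cell)     # atom - ghost
    r = np.maximum(np.linalg.norm(d, axis=-1), 1e-10)
    B, N = r.shape
    E = np.zeros(B)
    dE_datom = np.zeros((B, N, 3))
    for sign, A, sig, mask, rc in _ghost_terms(topo, params):
        u, up, _ = _ghost_radial(r, A, sig, rc)
        u = np.where(mask, u, 0.0)
        up = np.where(mask, up, 0.0)
        E += sign * u.sum(axis=1)
        dE_datom += sign * (up / r)[..., None] * d
    F_nuc = -dE_datom
    g_ghost = -dE_datom.sum(axis=1)     # dE/d(ghost) = -Σ dE/d(atom)
    return E, F_nuc, g_ghost


def _ghost_hessian(pos, ghost_pos, topo: _Topology, params: ToyModelParams):
    """Hessian of the ghost-coupling energy wrt the ghost position, (B, 3, 3)."""
    cell = topo.cell
    d = minimum_image(pos - ghost_pos[:, None, :], cell)
    r = np.maximum(np.linalg.norm(d, axis=-1), 1e-10)
    H = np.zeros((pos.shape[0], 3, 3))
    eye = np.eye(3)
    dhat = d / r[..., None]
    outer = dhat[..., :, None] * dhat[..., None, :]          # (B,N,3,3)
    for sign, A, sig, mask, rc in _ghost_terms(topo, params):
        u, up, upp = _ghost_radial(r, A, sig, rc)
        upp = np.where(mask, upp, 0.0)
        upr = np.where(mask, up / r, 0.0)
        H += sign * np.sum(upp[..., None, None] * outer +
                           upr[..., None, None] * (eye - outer), axis=1)
    return H


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def toy_energy_forces(config: Configuration, params: ToyModelParams,
                      ghost: GhostState | None = None) -> LabeledSample:
    """Reference energy and nuclear forces for one configuration.

    If a (relaxed) GhostState is supplied, the ghost-coupling energy and its
    nuclear forces are included; the sample's force sum then vanishes only to
    the extent the ghost gradient does — supply tightly converged states.
    """
    params.validate()
    topo = _Topology(config, params)
    gpos = None if ghost is None else np.asarray(ghost.position, float)[None, :]
    E, F = _toy_ef_batch(config.positions[None], topo, params, gpos)
    return LabeledSample(config, float(E[0]), F[0], has_ghost=ghost is not None)


def ghost_energy(config: Configuration, params: ToyModelParams,
                 position: np.ndarray) -> float:
    """Ghost-coupling energy at an arbitrary ghost position."""
    topo = _Topology(config, params)
    E, _, _ = _ghost_coupling(config.positions[None],
                              np.asarray(position, float)[None], topo, params)
    return float(E[0])


def _relax_ghost_batch(pos, ghost0, topo, params, gtol=1e-8, max_iter=200):
    """Damped-Newton relaxation of ghost positions, batched over replicas.

    pos: (B, N, 3); ghost0: (B, 3).  Returns (ghost (B,3), E (B,), grad_norm (B,),
    converged (B,)).  Levenberg-style damping guards against indefinite Hessians.
    """
    ghost = ghost0.copy()
    B = ghost.shape[0]
    lam = np.full(B, 1e-3)
    E, _, g = _ghost_coupling(pos, ghost, topo, params)
    eye = np.eye(3)
    for _ in range(max_iter):
        gn = np.linalg.norm(g, axis=1)
        active = gn > gtol
        if not np.any(active):
            break
        H = _ghost_hessian(pos, ghost, topo, params)
        step = np.zeros_like(ghost)
        for b in np.flatnonzero(active):
            Hb = H[b] + lam[b] * eye
            try:
                s = np.linalg.solve(Hb, -g[b])
            except np.linalg.LinAlgError:
                s = -g[b]
            # keep steps bounded; Gaussian landscape is smooth at the Å scale
            sn = np.linalg.norm(s)
            if sn > 1.0:
                s *= 1.0 / sn
            step[b] = s
        trial = ghost + step
        E_t, _, g_t = _ghost_coupling(pos, trial, topo, params)
        improved = (E_t < E + 1e-15) | ~active
        for b in range(B):
            if not active[b]:
                continue
            if improved[b]:
                ghost[b] = trial[b]
                E[b] = E_t[b]
                g[b] = g_t[b]
                lam[b] = max(lam[b] * 0.5, 1e-6)
            else:
                lam[b] = min(lam[b] * 10.0, 1e6)
    gn = np.linalg.norm(g, axis=1)
    return wrap_positions(ghost, topo.cell), E, gn, gn <= max(gtol, 1e-6)


def relax_ghost(config: Configuration, params: ToyModelParams,
                init: np.ndarray | None = None, n_starts: int = 8,
                gtol: float = 1e-8, max_iter: int = 200) -> GhostState:
    """Relax the ghost particle to a local minimum of its coupling energy.

    With ``init`` given (warm start, adiabatic continuity) a single local
    minimization is run.  Without it, an ``n_starts``-point grid over the cell
    seeds independent minimizations and the lowest minimum is returned.
    """
    params.validate()
    topo = _Topology(config, params)
    pos = config.positions[None]
    if init is not None:
        starts = np.asarray(init, float)[None, :]
    else:
        # corners of a 2×2×2 (or denser) fractional grid
        per_axis = max(2, int(round(n_starts ** (1 / 3))))
        fr = (np.arange(per_axis) + 0.5) / per_axis
        gx, gy, gz = np.meshgrid(fr, fr, fr, indexing="ij")
        starts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1) * config.cell
    posb = np.broadcast_to(pos, (len(starts),) + pos.shape[1:])
    ghost, E, gn, conv = _relax_ghost_batch(posb, starts, topo, params,
                                            gtol=gtol, max_iter=max_iter)
    best = int(np.argmin(np.where(conv, E, np.inf)))
    if not conv.any():
        best = int(np.argmin(E))
        logger.warning("ghost relaxation did not converge (|g|=%.2e)", gn[best])
    return GhostState(ghost[best], float(E[best]), bool(conv[best]),
                      float(gn[best]))


# ---------------------------------------------------------------------------
# potential objects (callable by the dynamics engines)
# ---------------------------------------------------------------------------

class ToyPotential:
    """Neat toy-fluid potential bound to a fixed composition/cell."""

    def __init__(self, config: Configuration, params: ToyModelParams):
        params.validate()
        self.params = params
        self.topology = _Topology(config, params)
        self.species = config.species
        self.cell = config.cell
        self.molecule_index = config.molecule_index

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    @property
    def max_frequency(self) -> float:
        """Highest harmonic angular frequency (the OH stretch), fs⁻¹."""
        from .units import ATOMIC_MASSES, MASS_EV
        m_o, m_h = ATOMIC_MASSES["O"], ATOMIC_MASSES["H"]
        mu = m_o * m_h / (m_o + m_h)
        return float(np.sqrt(self.params.k_bond / (mu * MASS_EV)))

    def energy_forces(self, positions: np.ndarray):
        """positions (N,3) or (B,N,3) → (E scalar or (B,), F same leading shape)."""
        single = positions.ndim == 2
        pos = positions[None] if single else positions
        E, F = _toy_ef_batch(pos, self.topology, self.params, None)
        return (float(E[0]), F[0]) if single else (E, F)


class AdiabaticGhostPotential(ToyPotential):
    """Toy fluid with the ghost relaxed on the fly for every evaluation.

    The ghost position is warm-started from the previous call (per replica),
    mirroring the adiabatic continuity of a quasiparticle following the
    nuclei.  ``last_ghosts`` exposes the relaxed positions for analysis.
    """

    def __init__(self, config: Configuration, params: ToyModelParams,
                 gtol: float = 1e-8):
        super().__init__(config, params)
        self.gtol = gtol
        self._warm: np.ndarray | None = None
        seed_state = relax_ghost(config, params, gtol=gtol)
        self._cold_start = seed_state.position
        self.last_ghosts: np.ndarray | None = None
        self.n_failed = 0

    def energy_forces(self, positions: np.ndarray):
        single = positions.ndim == 2
        pos = positions[None] if single else positions
        B = pos.shape[0]
        if self._warm is None or len(self._warm) != B:
            self._warm = np.tile(self._cold_start, (B, 1))
        ghost, Eg, gn, conv = _relax_ghost_batch(pos, self._warm, self.topology,
                                                 self.params, gtol=self.gtol)
        if not conv.all():
            self.n_failed += int((~conv).sum())
        self._warm = ghost.copy()
        self.last_ghosts = ghost
        E, F = _toy_ef_batch(pos, self.topology, self.params, ghost)
        return (float(E[0]), F[0]) if single else (E, F)


# ---------------------------------------------------------------------------
# box construction and dataset generation
# ---------------------------------------------------------------------------

WATER_MASS_G = 18.015 * 1.66053906660e-24   # grams per molecule


def cell_for_density(n_molecules: int, density: float) -> np.ndarray:
    """Cubic cell lengths (Å) for a given count and mass density (g/cm³)."""
    vol_cm3 = n_molecules * WATER_MASS_G / density
    L = vol_cm3 ** (1.0 / 3.0) * 1e8
    return np.array([L, L, L])


def _molecule_template(params: ToyModelParams) -> np.ndarray:
    """O at origin, H1/H2 in the xz plane at the equilibrium geometry."""
    half = params.theta0 / 2.0
    return np.array([
        [0.0, 0.0, 0.0],
        [params.r0 * np.sin(half), 0.0, params.r0 * np.cos(half)],
        [-params.r0 * np.sin(half), 0.0, params.r0 * np.cos(half)],
    ])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def build_box(n_molecules: int, density: float = 1.0, seed: int = 0,
              cell: np.ndarray | None = None, n_deuterium: int = 0,
              params: ToyModelParams | None = None,
              min_oo: float = 2.0, max_tries: int = 20000) -> Configuration:
    """Place molecules at random positions/orientations without O–O overlap.

    Deterministic for a fixed seed.  ``n_deuterium`` H sites (chosen at
    random) are relabeled D, allowing H2O/D2O/HOD mixtures.
    """
    if n_molecules < 1:
        raise GhostMDError("n_molecules must be >= 1")
    params = params or ToyModelParams()
    cell = np.asarray(cell, float) if cell is not None \
        else cell_for_density(n_molecules, density)
    rng = np.random.default_rng(seed)
    template = _molecule_template(params)
    o_positions: list[np.ndarray] = []
    positions = []
    for _ in range(n_molecules):
        for attempt in range(max_tries):
            if n_molecules == 1:
                o = cell / 2.0
            else:
                o = rng.uniform(0.0, 1.0, 3) * cell
            if all(np.linalg.norm(minimum_image(o - prev, cell)) >= min_oo
                   for prev in o_positions):
                break
        else:
            raise GhostMDError(
                f"packing failure: could not place molecule after {max_tries} tries")
        rot = _random_rotation(rng)
        positions.append(o + template @ rot.T)
        o_positions.append(o)
    pos = np.concatenate(positions, axis=0)
    species = np.array(["O", "H", "H"] * n_molecules, dtype="U2")
    mol = np.repeat(np.arange(n_molecules), 3)
    if n_deuterium:
        h_sites = np.flatnonzero(species == "H")
        if n_deuterium > len(h_sites):
            raise GhostMDError("n_deuterium exceeds available H sites")
        chosen = rng.choice(h_sites, size=n_deuterium, replace=False)
        species[chosen] = "D"
    config = Configuration(species, wrap_positions(pos, cell), cell, mol)
    config.validate()
    return config


def generate_dataset(params: ToyModelParams, n_samples: int,
                     sampler: str = "md", with_ghost: bool = True,
                     seed: int = 0, n_molecules: int = 32, density: float = 1.3,
                     temperature: float = 300.0, dt: float = 0.5,
                     stride: int = 20, equilibration: int = 400,
                     n_beads: int = 8, friction: float = 0.05,
                     sample_with_ghost: bool | None = None,
                     config: Configuration | None = None) -> Dataset:
    """Sample decorrelated configurations by MD/PIMD and label them.

    Frames are taken every ``stride`` steps from a Langevin (sampler='md') or
    thermostatted ring-polymer (sampler='pimd') trajectory driven by the toy
    potential.  ``sample_with_ghost`` picks the sampling surface (default:
    same as the labels); setting it False while ``with_ghost`` is True yields
    homogeneous-fluid frames labeled on the ghost surface — the out-of-basin
    states a ghost-free potential must know about to keep a cavity stable and
    to drive cavity formation after injection.  Each frame is labeled by
    :func:`toy_energy_forces`, with the ghost relaxed warm-started from the
    previous frame.  Frames whose ghost relaxation fails are dropped and
    logged.
    """
    from .dynamics import run_md, init_ring_polymer, run_trpmd, MDOptions

    if sampler not in ("md", "pimd"):
        raise GhostMDError(f"unknown sampler {sampler!r}")
    cfg = config.copy() if config is not None else build_box(
        n_molecules, density, seed=seed, params=params)
    if sample_with_ghost is None:
        sample_with_ghost = with_ghost
    pot = (AdiabaticGhostPotential(cfg, params) if sample_with_ghost
           else ToyPotential(cfg, params))
    steps = equilibration + n_samples * stride
    opts = MDOptions(dt=dt, steps=steps, temperature=temperature,
                     thermostat="langevin", friction=friction, seed=seed,
                     stride=stride, store_velocities=False)
    if sampler == "md":
        traj = run_md(cfg, pot, opts)
        frames = traj.positions
    else:
        state = init_ring_polymer(cfg, n_beads, temperature, seed=seed)
        traj = run_trpmd(state, pot, opts, store_beads=True)
        # one randomly chosen bead per stored frame: bead configurations are
        # the physically distorted samples quantum sampling is meant to add
        rng = np.random.default_rng(seed + 1)
        picks = rng.integers(0, n_beads, size=len(traj.bead_positions))
        frames = np.stack([bp[k] for bp, k in zip(traj.bead_positions, picks)])

    skip = max(1, equilibration // stride)
    frames = frames[skip:]
    samples: list[LabeledSample] = []
    warm = None
    for fpos in frames:
        fcfg = cfg.with_positions(wrap_positions(fpos, cfg.cell))
        ghost = None
        if with_ghost:
            ghost = relax_ghost(fcfg, params,
                                init=warm if warm is not None else None)
            if not ghost.converged:
                logger.warning("dropping frame: ghost relaxation failed "
                               "(|g|=%.2e)", ghost.grad_norm)
                warm = None
                continue
            warm = ghost.position
        samples.append(toy_energy_forces(fcfg, params, ghost))
        if len(samples) == n_samples:
            break
    meta = dict(sampler=sampler, with_ghost=with_ghost, seed=seed,
                n_molecules=cfg.n_molecules, temperature=temperature,
                dt=dt, stride=stride, params=params.to_dict())
    return Dataset(samples, has_ghost=with_ghost, metadata=meta)


def standard_training_mixture(params: ToyModelParams, seed: int = 0,
                              n_molecules: int = 32, density: float = 1.3,
                              scale: float = 1.0) -> Dataset:
    """The frozen training-set recipe for the electron (ghost) potential.

    Four strata, all labeled on the adiabatic-ghost surface:

    - ``cavity``: equilibrated adiabatic-ghost MD (the stable solvated state);
    - ``localization``: short ghost-MD segments started from *neat* fluid
      configurations, sampled without equilibration — the cavity-opening
      pathway, with continuous warm-started ghost tracks and therefore
      well-defined forces;
    - ``homogeneous``: neat-MD frames relabeled with the globally relaxed
      ghost; their energies carry the cavity-collapse penalty but their
      forces inherit the multi-basin ambiguity of the ghost minimum, so
      training supervises them through energies only;
    - ``cavity_pimd``: ring-polymer-sampled cavity frames (quantum-broadened
      configurations).

    ``scale`` shrinks every stratum proportionally (testing use).
    """
    n_cav = max(2, int(450 * scale))
    n_loc = max(2, int(250 * scale))
    n_hom = max(2, int(120 * scale))
    n_pi = max(2, int(100 * scale))
    n_wall = max(2, int(170 * scale))
    common = dict(n_molecules=n_molecules, density=density)
    parts = [
        # long-stride cavity sampling: ~30 ps of adiabatic-ghost dynamics, so
        # the slow cavity-size fluctuations are represented, not just one window
        generate_dataset(params, n_cav, sampler="md", with_ghost=True,
                         seed=seed, stride=60, **common),
        Dataset.concat([
            generate_dataset(params, n_loc // 6, sampler="md", with_ghost=True,
                             seed=seed + 100 + k, equilibration=0, stride=10,
                             **common)
            for k in range(6)]),
        generate_dataset(params, n_hom, sampler="md", with_ghost=True,
                         sample_with_ghost=False, seed=seed + 1, **common),
        generate_dataset(params, n_pi, sampler="pimd", with_ghost=True,
                         seed=seed + 2, n_beads=8, **common),
    ]
    parts.append(wall_probe_samples(params, parts[0], n_wall, seed=seed + 3))
    return Dataset.concat(
        parts, labels=["cavity", "localization", "homogeneous", "cavity_pimd",
                       "wall"])


def wall_probe_samples(params: ToyModelParams, base: Dataset, n_probes: int,
                       seed: int = 0, max_disp: float = 1.1) -> Dataset:
    """Cavity frames with one shell molecule perturbed against the solute.

    MD sampling alone rarely visits either the repulsive approach of an O
    site toward the cavity center or strongly disoriented shell molecules,
    yet the wall and the orientational restoring torque are exactly what
    keep the learned cavity open and H-lined.  Probes alternate between
    (a) dragging a near-center molecule radially inward by up to
    ``max_disp`` Å and (b) rigidly rotating a shell molecule about its O
    site by 30–150°.  Each probe is relabeled with the ghost re-relaxed from
    the original center (same basin), so energies and forces are well
    defined; probes that violate the hard floor or kick the ghost to a
    different basin are skipped.
    """
    rng = np.random.default_rng(seed)
    samples: list[LabeledSample] = []
    order = rng.permutation(len(base))
    for k, idx in enumerate(order):
        if len(samples) >= n_probes:
            break
        cfg = base.samples[idx].configuration
        g0 = relax_ghost(cfg, params)
        d = cfg.distances_to(g0.position)
        o_idx = np.flatnonzero(cfg.is_element("O") & (d < 4.3))
        if len(o_idx) == 0:
            continue
        o = int(rng.choice(o_idx))
        sel = cfg.molecule_index == cfg.molecule_index[o]
        probe = cfg.copy()
        if k % 2 == 0:
            # translation probe: compress the cavity wall
            u = minimum_image(g0.position - cfg.positions[o], cfg.cell)
            u /= np.linalg.norm(u)
            probe.positions[sel] += rng.uniform(0.25, max_disp) * u
        else:
            # rotation probe: disorient the lined OH about its O site
            angle = rng.uniform(np.pi / 6, 5 * np.pi / 6)
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
            rel = minimum_image(probe.positions[sel] - probe.positions[o],
                                probe.cell)
            probe.positions[sel] = probe.positions[o] + rel @ R.T
        g1 = relax_ghost(probe, params, init=g0.position)
        if not g1.converged or np.linalg.norm(
                minimum_image(g1.position - g0.position, cfg.cell)) > 1.2:
            continue
        try:
            samples.append(toy_energy_forces(probe, params, g1))
        except GhostMDError:
            continue
    return Dataset(samples, has_ghost=True,
                   metadata=dict(base.metadata, probe_seed=seed))


#: per-label loss weights matching :func:`standard_training_mixture`:
#: homogeneous frames are supervised through energies only (their ghost-relaxed
#: forces are multi-basin ambiguous) and upweighted so the cavity-collapse
#: penalty competes with the majority strata; localization-path forces are
#: upweighted because they carry the cavity-wall region
STANDARD_FORCE_WEIGHTS = {"homogeneous": 0.0, "localization": 2.0,
                          "wall": 2.0}
STANDARD_ENERGY_WEIGHTS = {"homogeneous": 10.0}
#: global energy/force balance for the standard electron training: the force
#: term is ~70x the per-atom energy term in absolute units, so a small w still
#: leaves force matching dominant while letting the energy strata act
STANDARD_FORCE_WEIGHT = 0.10
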