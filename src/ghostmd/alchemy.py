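"""Quantum alchemical H↔D exchange and isotope fractionation at the cavity.

Because the physical potential is mass-independent, exchanging the masses of
an H and a D site at fixed ring-polymer geometry changes only the bead-spring
energy; the Metropolis acceptance for a swap is therefore

    P_acc = min(1, exp(−ΔE_spring / (k_B·P·T)))

(the extended bead system is sampled at temperature P·T in this package's
convention).  Velocities of swapped atoms are rescaled by √(m_old/m_new),
which maps a Maxwell distribution at the old mass onto the new one exactly,
so detailed balance holds for the full state.

Alternating TRPMD segments with swap sweeps equilibrates the isotope
distribution; classifying H sites as cavity-shell or bulk around a tracked
void center yields the fractionation equilibrium constant

    K_eq = (n_H/n_D)_shell / (n_H/n_D)_bulk,

the odds ratio for finding H rather than D at a shell site.  K_eq > 1 means
the light isotope is enriched at the cavity, the regime where the solute
red-shifts the local stretching frequency enough to favor the isotope with
the larger zero-point energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dynamics import MDOptions, RingPolymerState, run_trpmd
from .system import GhostMDError, minimum_image
from .units import ATOMIC_MASSES, HBAR, KB, MASS_EV

logger = logging.getLogger(__name__)


@dataclass
class AlchemyOptions:
    md_steps: int = 60            # TRPMD steps between swap sweeps
    n_sweeps: int = 200           # number of (segment + sweep) cycles
    shell_radius: float = 3.5     # Å, H sites within this of the center = shell
    dt: float = 0.5               # fs
    friction: float = 0.05        # centroid friction during segments (sampling)
    seed: int = 0
    equil_sweeps: int = 20        # cycles discarded before accumulating
    n_bootstrap: int = 200
    center_mode: str = "ghost"    # 'ghost' | 'void' | 'fixed'
    fixed_center: np.ndarray | None = None
    grid_spacing: float = 0.45


@dataclass
class AlchemyResult:
    occupancy: np.ndarray         # (n_sweeps, n_sites) bool, True = H
    shell_mask: np.ndarray        # (n_sweeps, n_sites) bool
    site_atoms: np.ndarray        # H/D atom indices tracked
    acceptance_rate: float
    K_eq: float | None            # occupancy-odds estimator
    K_ci: tuple | None            # bootstrap (2.5%, 97.5%)
    bulk_only: bool               # True when no cavity was ever detected
    centers: np.ndarray | None = None
    #: variance-reduced virtual-substitution (free-energy-perturbation)
    #: estimate of the same constant: every site contributes a mass-mutation
    #: weight every sweep instead of only realized swap outcomes
    K_fep: float | None = None
    K_fep_ci: tuple | None = None


def spring_energy(state: RingPolymerState, atom: int) -> float:
    """Ring-polymer spring energy of one atom (eV).

    E = Σ_b ½ m ω_P² |r_{b+1} − r_b|² with ω_P = P·k_B·T/ħ and cyclic beads;
    zero for P = 1 (classical limit).
    """
    P = state.n_beads
    if P < 2:
        return 0.0
    omega_P = P * KB * state.temperature / HBAR
    d = state.positions[:, atom, :] - np.roll(state.positions[:, atom, :], -1,
                                              axis=0)
    return float(0.5 * state.masses[atom] * MASS_EV * omega_P ** 2 *
                 np.sum(d * d))


def _bead_spread(state: RingPolymerState, atom: int) -> float:
    """Σ_b |r_{b+1} − r_b|² (geometry factor of the spring energy)."""
    d = state.positions[:, atom, :] - np.roll(state.positions[:, atom, :], -1,
                                              axis=0)
    return float(np.sum(d * d))


def attempt_swap(state: RingPolymerState, site_h: int, site_d: int,
                 rng: np.random.Generator) -> bool:
    """Metropolis mass exchange between an H site and a D site.

    On acceptance masses are exchanged in place and the two atoms' velocities
    rescaled by √(m_old/m_new).  Equal masses are always accepted (ΔE = 0).
    """
    P = state.n_beads
    m_h = state.masses[site_h]
    m_d = state.masses[site_d]
    omega_P = P * KB * state.temperature / HBAR
    dE = 0.5 * MASS_EV * omega_P ** 2 * (m_d - m_h) * \
        (_bead_spread(state, site_h) - _bead_spread(state, site_d))
    beta_ext = 1.0 / (KB * P * state.temperature)
    accept = dE <= 0 or rng.random() < np.exp(-beta_ext * dE)
    if accept:
        state.masses[site_h], state.masses[site_d] = m_d, m_h
        state.velocities[:, site_h, :] *= np.sqrt(m_h / m_d)
        state.velocities[:, site_d, :] *= np.sqrt(m_d / m_h)
        sp = state.species[site_h]
        state.species[site_h] = state.species[site_d]
        state.species[site_d] = sp
    return bool(accept)


def _track_center(state: RingPolymerState, potential, opts: AlchemyOptions):
    """Current cavity center or None (mode-dependent)."""
    if opts.center_mode == "fixed":
        return np.asarray(opts.fixed_center, float)
    if opts.center_mode == "ghost":
        ghosts = getattr(potential, "last_ghosts", None)
        if ghosts is not None:
            # centroid of the per-bead ghost positions (min-image about bead 0)
            ref = ghosts[0]
            rel = minimum_image(ghosts - ref, state.cell)
            return ref + rel.mean(axis=0)
        return None
    from .analysis import void_center
    rec = void_center(state.config(), opts.grid_spacing)
    return rec.centers[0] if rec.n_centers else None


def run_alchemy(state: RingPolymerState, potential,
                opts: AlchemyOptions | None = None) -> AlchemyResult:
    """Alternate TRPMD segments and H/D swap sweeps; estimate K_eq.

    Each sweep makes n_H random H/D pair attempts.  H sites are classified
    shell/bulk by distance of their bead centroid to the tracked cavity
    center; when no center is ever found the run degrades to a bulk-only
    null (K_eq reported as None).
    """
    opts = opts or AlchemyOptions()
    if state.n_beads < 2:
        raise GhostMDError("alchemy requires P >= 2 (spring energies vanish)")
    is_site = np.isin(state.species, ("H", "D"))
    site_atoms = np.flatnonzero(is_site)
    n_h = int(np.sum(state.species == "H"))
    n_d = int(np.sum(state.species == "D"))
    if n_h == 0 or n_d == 0:
        raise GhostMDError("alchemy needs a mixed H/D composition")
    rng = np.random.default_rng(opts.seed)

    occ, shell, centers = [], [], []
    spreads = []
    n_acc = 0
    n_att = 0
    md_opts = MDOptions(dt=opts.dt, steps=opts.md_steps,
                        temperature=state.temperature, thermostat="langevin",
                        friction=opts.friction, stride=opts.md_steps,
                        store_velocities=False)
    total = opts.equil_sweeps + opts.n_sweeps
    for sweep in range(total):
        md_opts.seed = int(rng.integers(2 ** 31))
        traj = run_trpmd(state, potential, md_opts)
        state = traj.final_state
        h_sites = np.flatnonzero(state.species == "H")
        d_sites = np.flatnonzero(state.species == "D")
        for _ in range(len(h_sites)):
            sh = int(rng.choice(np.flatnonzero(state.species == "H")))
            sd = int(rng.choice(np.flatnonzero(state.species == "D")))
            n_acc += attempt_swap(state, sh, sd, rng)
            n_att += 1
        if sweep < opts.equil_sweeps:
            continue
        center = _track_center(state, potential, opts)
        centroid = state.centroid
        d_bead = state.positions[:, site_atoms, :] - \
            np.roll(state.positions, -1, axis=0)[:, site_atoms, :]
        spreads.append(np.sum(d_bead * d_bead, axis=(0, 2)))
        occ.append(state.species[site_atoms] == "H")
        if center is None:
            shell.append(np.zeros(len(site_atoms), dtype=bool))
            centers.append(np.full(3, np.nan))
        else:
            d = np.linalg.norm(minimum_image(centroid[site_atoms] - center,
                                             state.cell), axis=1)
            shell.append(d <= opts.shell_radius)
            centers.append(center)

    occ = np.array(occ)
    shell = np.array(shell)
    spreads = np.array(spreads)
    acc_rate = n_acc / max(1, n_att)
    if not shell.any():
        logger.warning("no cavity detected at any sweep: bulk-only null")
        return AlchemyResult(occ, shell, site_atoms, acc_rate, None, None,
                             True, np.array(centers))
    rng_b = np.random.default_rng(opts.seed + 1)
    K, ci = _keq_bootstrap(occ, shell, opts.n_bootstrap, rng_b)
    K_fep, fep_ci = _keq_fep(occ, shell, spreads, state.n_beads,
                             state.temperature, opts.n_bootstrap, rng_b)
    return AlchemyResult(occ, shell, site_atoms, acc_rate, K, ci, False,
                         np.array(centers), K_fep=K_fep, K_fep_ci=fep_ci)


def estimate_autocorr_sweeps(series: np.ndarray, cap: int = 50) -> int:
    """Integrated autocorrelation time (in sweeps) of a scalar series."""
    x = series - series.mean()
    if np.allclose(x, 0):
        return 1
    acf = np.correlate(x, x, mode="full")[len(x) - 1:]
    acf /= acf[0]
    tau = 1.0
    for k in range(1, min(len(acf), cap)):
        if acf[k] < 0.05:
            break
        tau += 2.0 * acf[k]
    return max(1, int(np.ceil(tau)))


def _keq_counts(occ, shell):
    nh_s = float(np.sum(occ & shell))
    nd_s = float(np.sum(~occ & shell))
    nh_b = float(np.sum(occ & ~shell))
    nd_b = float(np.sum(~occ & ~shell))
    if min(nh_s, nd_s, nh_b, nd_b) == 0:
        nh_s += 0.5
        nd_s += 0.5
        nh_b += 0.5
        nd_b += 0.5
    return (nh_s / nd_s) / (nh_b / nd_b)


def _keq_fep(occ, shell, spreads, P, temperature, n_boot, rng):
    """Virtual-substitution estimate of K_eq.

    For every H site the mass mutation H→D changes only the spring energy,
    ΔE = ½ ω_P² Δm S (S the bead-spread geometry factor), so the mutation
    free energy per site class is −k_B T_ext·ln⟨e^{−β_ext ΔE}⟩; D sites
    contribute the reverse mutation.  K_eq = exp(β_ext(Δf_shell − Δf_bulk))
    uses every site at every sweep and therefore resolves fractionation
    constants far closer to 1 than realized swap occupancies can.
    """
    omega_p = P * KB * temperature / HBAR
    c = 0.5 * MASS_EV * omega_p**2 * (ATOMIC_MASSES["D"] - ATOMIC_MASSES["H"])
    beta = 1.0 / (KB * P * temperature)
    w_fwd = np.exp(-beta * c * spreads)      # H→D weight
    w_rev = np.exp(+beta * c * spreads)      # D→H weight

    def estimate(sel):
        out = []
        for mask_cls in (shell[sel], ~shell[sel]):
            o = occ[sel]
            f = w_fwd[sel]
            r = w_rev[sel]
            h = mask_cls & o
            d = mask_cls & ~o
            lf = np.log(f[h].mean()) if h.any() else None
            lr = np.log(r[d].mean()) if d.any() else None
            out.append((lf, lr))
        (lf_s, lr_s), (lf_b, lr_b) = out
        # forward: K = <w>_bulk/<w>_shell; reverse mutation gives the inverse
        terms = []
        if lf_s is not None and lf_b is not None:
            terms.append(lf_b - lf_s)
        if lr_s is not None and lr_b is not None:
            terms.append(lr_s - lr_b)
        if not terms:
            return None
        return float(np.exp(np.mean(terms)))

    n = len(occ)
    K = estimate(np.arange(n))
    if K is None:
        return None, None
    samples = []
    for _ in range(n_boot):
        sel = rng.integers(0, n, size=n)
        k = estimate(sel)
        if k is not None:
            samples.append(k)
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return K, (float(lo), float(hi))


def _keq_bootstrap(occ, shell, n_boot, rng):
    """Pooled-count K_eq with a block bootstrap over decorrelated sweeps."""
    shell_h = (occ & shell).sum(axis=1).astype(float)
    tau = estimate_autocorr_sweeps(shell_h)
    block = max(1, 10 * tau)
    n = len(occ)
    n_blocks = max(1, n // block)
    K = _keq_counts(occ, shell)
    if n_blocks < 2:
        logger.warning("fewer than 2 bootstrap blocks; CI is unreliable")
    samples = []
    for _ in range(n_boot):
        picks = rng.integers(0, n_blocks, size=n_blocks)
        idx = np.concatenate([np.arange(p * block, min((p + 1) * block, n))
                              for p in picks])
        samples.append(_keq_counts(occ[idx], shell[idx]))
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return float(K), (float(lo), float(hi))
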