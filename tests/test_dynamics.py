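"""MD/TRPMD engines: symplectic conservation, thermostats, quantum statistics."""

import numpy as np
import pytest

from ghostmd.dynamics import (MDOptions, RingPolymerState, init_ring_polymer,
                              injection_run, normal_mode_matrix,
                              ring_frequencies, run_md, run_trpmd,
                              spring_potential_energy)
from ghostmd.system import Configuration, GhostMDError
from ghostmd.units import HBAR, KB, MASS_EV


class Harmonic:
    """Isotropic harmonic well about the origin (per bead)."""

    def __init__(self, k):
        self.k = k

    def energy_forces(self, pos):
        return 0.5 * self.k * np.sum(pos**2, axis=(-1, -2)), -self.k * pos


class Free:
    def energy_forces(self, pos):
        return np.zeros(pos.shape[:-2]), np.zeros_like(pos)


def one_atom_config(mass_label="H"):
    cfg = Configuration([mass_label], [[0.0, 0.0, 0.0]], [1e6] * 3, [0])
    return cfg


def one_atom_state(x0, v0, mass, T, P=1):
    pos = np.tile(np.asarray(x0, float), (P, 1, 1))
    vel = np.tile(np.asarray(v0, float), (P, 1, 1))
    return RingPolymerState(pos, vel, np.array([mass]), T,
                            np.array(["H"]), np.array([1e6] * 3), np.array([0]))


class TestClassicalMD:
    def test_nve_energy_conservation_1e6_relative(self):
        # ω·dt = 3e-3: the velocity-Verlet energy oscillation stays below 1e-6
        m, dt = 1.0, 1.0
        omega = 3e-3
        k = m * MASS_EV * omega**2
        state = one_atom_state([[0.5, 0, 0]], [[0, 0.001, 0]], m, 300.0)
        traj = run_trpmd(state, Harmonic(k),
                         MDOptions(dt=dt, steps=100000, thermostat="none",
                                   stride=500), record_conserved=True)
        E = traj.total_energy
        assert np.abs(E - E[0]).max() / abs(E[0]) < 1e-6

    def test_langevin_equipartition_free_particle(self):
        T, m = 250.0, 2.0
        cfg = one_atom_config()
        traj = run_md(cfg, Free(),
                      MDOptions(dt=1.0, steps=40000, temperature=T,
                                thermostat="langevin", friction=0.2, seed=4,
                                stride=5))
        # override mass: config H has m=1.008; build explicit state instead
        state = one_atom_state([[0, 0, 0]], [[0, 0, 0]], m, T)
        traj = run_trpmd(state, Free(),
                         MDOptions(dt=1.0, steps=40000, temperature=T,
                                   thermostat="langevin", friction=0.2, seed=4,
                                   stride=5))
        v2 = traj.velocities[200:] ** 2
        target = KB * T / (m * MASS_EV)
        blocks = np.array_split(v2.reshape(-1), 8)
        means = np.array([b.mean() for b in blocks])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(v2.mean() - target) < 3 * se + 1e-12

    def test_bitwise_deterministic_per_seed(self, small_box, tiny_params):
        from ghostmd.toy import ToyPotential
        pot = ToyPotential(small_box, tiny_params)
        opts = MDOptions(dt=0.4, steps=60, temperature=300,
                         thermostat="langevin", friction=0.1, seed=11, stride=10)
        t1 = run_md(small_box, pot, opts)
        t2 = run_md(small_box, pot, opts)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.velocities, t2.velocities)

    def test_timestep_resolution_guard(self, small_box, tiny_params):
        from ghostmd.toy import ToyPotential
        pot = ToyPotential(small_box, tiny_params)
        with pytest.raises(GhostMDError, match="steps/period"):
            run_md(small_box, pot, MDOptions(dt=2.0, steps=10))

    def test_nonfinite_forces_abort(self):
        class Broken:
            def energy_forces(self, pos):
                return np.full(pos.shape[:-2], np.nan), np.full_like(pos, np.nan)

        state = one_atom_state([[0, 0, 0]], [[0, 0, 0]], 1.0, 300.0)
        with pytest.raises(GhostMDError, match="non-finite"):
            run_trpmd(state, Broken(), MDOptions(dt=0.5, steps=5))


class TestRingPolymerSetup:
    def test_p1_beads_equal_configuration(self):
        cfg = one_atom_config()
        state = init_ring_polymer(cfg, 1, 300.0, seed=0)
        np.testing.assert_array_equal(state.positions[0], cfg.positions)

    def test_fixed_seed_reproducible(self):
        cfg = one_atom_config()
        a = init_ring_polymer(cfg, 8, 300.0, seed=5)
        b = init_ring_polymer(cfg, 8, 300.0, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.velocities, b.velocities)

    def test_free_polymer_gyration_matches_mode_sum_oracle(self):
        """Sampled bead spread vs the exact normal-mode variance sum
        r_g² = (3/P)·Σ_{k>0} k_B P T/(m ω_k²)."""
        P, T, m = 32, 200.0, 1.008
        cfg = one_atom_config()
        omegas = ring_frequencies(P, T)
        exact = 3.0 / P * np.sum(KB * P * T / (m * MASS_EV * omegas[1:] ** 2))
        sampled = []
        for seed in range(300):
            st = init_ring_polymer(cfg, P, T, seed=seed)
            rel = st.positions[:, 0, :] - st.positions[:, 0, :].mean(axis=0)
            sampled.append(np.mean(np.sum(rel**2, axis=1)) * P / P)
        sampled = np.mean(sampled) * 1.0
        # mean over beads of |r-centroid|^2 equals r_g^2
        assert sampled == pytest.approx(exact, rel=0.1)

    def test_heavier_isotope_shrinks_polymer_by_sqrt_mass(self):
        cfg_h = one_atom_config("H")
        cfg_d = one_atom_config("D")
        spreads = {}
        for cfg, lab in ((cfg_h, "H"), (cfg_d, "D")):
            acc = []
            for seed in range(200):
                st = init_ring_polymer(cfg, 16, 300.0, seed=seed)
                rel = st.positions[:, 0, :] - st.positions[:, 0, :].mean(axis=0)
                acc.append(np.mean(np.sum(rel**2, axis=1)))
            spreads[lab] = np.mean(acc)
        ratio = np.sqrt(spreads["H"] / spreads["D"])
        assert ratio == pytest.approx(np.sqrt(2.014 / 1.008), rel=0.08)


class TestTRPMD:
    def test_p1_bit_compatible_with_classical_md(self, small_box, tiny_params):
        from ghostmd.toy import ToyPotential
        pot = ToyPotential(small_box, tiny_params)
        opts = MDOptions(dt=0.4, steps=40, temperature=300,
                         thermostat="langevin", friction=0.1, seed=3, stride=5)
        t_md = run_md(small_box, pot, opts)
        state = init_ring_polymer(small_box, 1, 300.0, seed=3)
        t_rp = run_trpmd(state, pot, opts)
        np.testing.assert_array_equal(t_md.positions, t_rp.positions)

    def test_free_ring_polymer_conserves_hamiltonian(self):
        state = init_ring_polymer(one_atom_config(), 16, 300.0, seed=1)
        traj = run_trpmd(state, Free(),
                         MDOptions(dt=0.5, steps=10000, thermostat="none",
                                   stride=200), record_conserved=True)
        E = traj.total_energy
        assert np.abs(E - E[0]).max() / abs(E[0]) < 1e-8

    def test_quantum_harmonic_position_variance(self):
        """P=64 TRPMD reproduces <x²> = (ħ/2mω)·coth(βħω/2) at βħω = 5."""
        T, m = 300.0, 1.008
        beta = 1.0 / (KB * T)
        omega = 5.0 / (beta * HBAR)
        k = m * MASS_EV * omega**2
        state = init_ring_polymer(one_atom_config(), 64, T, seed=1)
        traj = run_trpmd(state, Harmonic(k),
                         MDOptions(dt=1.0, steps=50000, thermostat="langevin",
                                   friction=0.05, seed=2, stride=5),
                         store_beads=True)
        x2 = np.mean(traj.bead_positions[40:] ** 2)
        exact = HBAR / (2 * m * MASS_EV * omega) / np.tanh(beta * HBAR * omega / 2)
        assert x2 == pytest.approx(exact, rel=0.02)

    def test_classical_limit_p1(self):
        T, m = 300.0, 1.008
        beta = 1.0 / (KB * T)
        omega = 5.0 / (beta * HBAR)
        k = m * MASS_EV * omega**2
        state = init_ring_polymer(one_atom_config(), 1, T, seed=6)
        traj = run_trpmd(state, Harmonic(k),
                         MDOptions(dt=1.0, steps=60000, thermostat="langevin",
                                   friction=0.2, seed=7, stride=5),
                         store_beads=True)
        x2 = np.mean(traj.bead_positions[100:] ** 2)
        assert x2 == pytest.approx(KB * T / (m * MASS_EV * omega**2), rel=0.03)

    def test_normal_mode_matrix_is_orthonormal(self):
        for P in (1, 2, 5, 8):
            C, _ = normal_mode_matrix(P)
            np.testing.assert_allclose(C @ C.T, np.eye(P), atol=1e-12)

    def test_spring_energy_zero_for_collapsed_beads(self):
        state = one_atom_state([[1.0, 2.0, 3.0]], [[0, 0, 0]], 1.0, 300.0, P=4)
        assert spring_potential_energy(state) == 0.0


class TestInjection:
    def test_event_log_reproducible_and_null_protocol_quiet(self, small_box,
                                                            tiny_params):
        from ghostmd.dynamics import InjectionOptions
        from ghostmd.toy import ToyPotential
        pot = ToyPotential(small_box, tiny_params)
        opts = InjectionOptions(equil_steps=30, production_steps=60,
                                n_replicas=2, seeds=[0, 1], dt=0.4,
                                stride=20, radius_threshold=2.55,
                                grid_spacing=0.5)
        t1, e1 = injection_run(small_box, pot, pot, opts)
        t2, e2 = injection_run(small_box, pot, pot, opts)
        assert [e["event_time"] for e in e1] == [e["event_time"] for e in e2]
        np.testing.assert_array_equal(e1[0]["radius_series"],
                                      e2[0]["radius_series"])

    def test_size_mismatch_rejected(self, small_box, tiny_params):
        from ghostmd.dynamics import InjectionOptions
        from ghostmd.toy import ToyPotential, build_box
        pot_a = ToyPotential(small_box, tiny_params)
        other = build_box(6, density=1.3, seed=0, params=tiny_params,
                          cell=small_box.cell)
        pot_b = ToyPotential(other, tiny_params)
        with pytest.raises(GhostMDError, match="size"):
            injection_run(small_box, pot_a, pot_b, InjectionOptions())
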