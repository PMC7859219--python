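"""Observables: void detection, RDFs, gyration, MSD, VDOS, hydrogen bonds."""

import numpy as np
import pytest

from ghostmd.analysis import (HBParams, Spectrum, coordination_number,
                              gyration_stats, hb_state, msd_diffusion,
                              pair_rdf, peak_metrics, rdf_about_centers,
                              shell_members, track_cavities, vdos,
                              void_center, _msd_fft)
from ghostmd.dynamics import Trajectory
from ghostmd.system import Configuration, GhostMDError, minimum_image
from ghostmd.units import C_CM_FS


def atom_cloud(positions, cell):
    """Bare point-atom Configuration (no molecular structure needed here)."""
    n = len(positions)
    return Configuration(["O"] * n, positions, cell, np.arange(n))


def lattice_with_vacancies(n, spacing, vacancies):
    idx = [(i, j, k) for i in range(n) for j in range(n) for k in range(n)
           if (i, j, k) not in vacancies]
    pos = np.array(idx, dtype=float) * spacing
    return atom_cloud(pos, np.array([n * spacing] * 3))


def make_traj(frames, cell, times=None, velocities=None, masses=None):
    frames = np.asarray(frames, float)
    n = frames.shape[1]
    return Trajectory(
        np.asarray(times if times is not None else np.arange(len(frames)),
                   float),
        frames, np.asarray(cell, float), np.array(["O"] * n), np.arange(n),
        velocities=None if velocities is None else np.asarray(velocities),
        metadata=dict(masses=masses if masses is not None else np.ones(n)))


class TestVoidCenter:
    def test_vacancy_in_cubic_lattice(self):
        a = 2.5
        cfg = lattice_with_vacancies(4, a, {(1, 2, 1)})
        rec = void_center(cfg, grid_spacing=0.4, radius_threshold=2.0)
        assert rec.n_centers >= 1
        d = np.linalg.norm(minimum_image(
            rec.centers[0] - np.array([1, 2, 1]) * a, cfg.cell))
        assert d < 0.15
        assert rec.maximin_radii[0] == pytest.approx(a, rel=0.02)

    def test_dense_random_fluid_has_no_large_void(self):
        rng = np.random.default_rng(0)
        cell = np.array([10.0] * 3)
        cfg = atom_cloud(rng.uniform(0, 10, size=(500, 3)), cell)
        rec = void_center(cfg, grid_spacing=0.3, radius_threshold=2.0)
        # brute-force confirmation on a fine grid
        from scipy.spatial import cKDTree
        tree = cKDTree(cfg.positions, boxsize=cell)
        g = np.arange(0, 10.0, 0.2)
        pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)
        assert tree.query(pts)[0].max() < 2.0
        assert rec.n_centers == 0

    def test_two_distant_vacancies_not_twin(self):
        a = 2.5
        cfg = lattice_with_vacancies(6, a, {(1, 1, 1), (4, 4, 4)})
        rec = void_center(cfg, grid_spacing=0.45, radius_threshold=2.0,
                          pairing_cutoff=6.0)
        assert rec.n_centers == 2
        assert not rec.twin

    def test_translation_covariance(self):
        a = 2.6
        cfg = lattice_with_vacancies(4, a, {(2, 1, 2)})
        rec0 = void_center(cfg, 0.4, radius_threshold=2.0)
        v = np.array([1.1, -0.6, 2.3])
        shifted = cfg.copy()
        shifted.positions = shifted.positions + v
        rec1 = void_center(shifted, 0.4, radius_threshold=2.0)
        d = minimum_image(rec1.centers[0] - rec0.centers[0] - v, cfg.cell)
        assert np.linalg.norm(d) < 0.2

    def test_empty_record_for_filled_lattice(self):
        # a filled simple-cubic lattice still has interstitial voids of radius
        # a·√3/2 ≈ 2.17; above that nothing qualifies
        cfg = lattice_with_vacancies(4, 2.5, set())
        rec = void_center(cfg, 0.45, radius_threshold=2.3)
        assert rec.n_centers == 0 and not rec.twin


class TestTrackCavities:
    def test_constant_center_for_static_frames(self):
        cfg = lattice_with_vacancies(4, 2.5, {(1, 1, 1)})
        traj = make_traj([cfg.positions] * 4, cfg.cell)
        records, events = track_cavities(traj, 0.45, radius_threshold=2.0)
        assert all(r.n_centers >= 1 for r in records)
        assert len(events["switches"]) == 0

    def test_twin_interval_and_identity_switch(self):
        """Void A → A+B → B: the middle frame is a twin, and the primary
        identity switches once."""
        a = 2.6
        fA = lattice_with_vacancies(6, a, {(1, 1, 1)})
        fAB = lattice_with_vacancies(6, a, {(1, 1, 1), (3, 1, 1)})
        fB = lattice_with_vacancies(6, a, {(3, 1, 1)})
        recs = [void_center(f, 0.45, radius_threshold=2.4, pairing_cutoff=6.0)
                for f in (fA, fAB, fB)]
        assert not recs[0].twin and recs[1].twin and not recs[2].twin
        posA = np.array([1, 1, 1]) * a
        posB = np.array([3, 1, 1]) * a
        dA0 = np.linalg.norm(minimum_image(recs[0].centers[0] - posA, fA.cell))
        dB2 = np.linalg.norm(minimum_image(recs[2].centers[0] - posB, fB.cell))
        assert dA0 < 1.0 and dB2 < 1.0


class TestRDF:
    def test_ideal_gas_is_unity_and_counts_match_brute_force(self):
        rng = np.random.default_rng(1)
        cell = [12.0] * 3
        n_frames = 400
        frames = rng.uniform(0, 12.0, size=(n_frames, 1000, 3))
        traj = make_traj(frames, cell)
        centers = [rng.uniform(0, 12.0, size=(1, 3)) for _ in range(n_frames)]
        rdf = rdf_about_centers(traj, centers, "O", r_max=5.5, n_bins=11)
        assert np.abs(rdf.g[rdf.r > 1.0] - 1.0).max() < 0.05
        assert np.abs(np.mean(rdf.g[rdf.r > 1.0]) - 1.0) < 0.01
        # n(r_max) equals the brute-force average count within r_max
        count = 0
        for f, c in zip(frames, centers):
            d = np.linalg.norm(minimum_image(f - c[0], np.array(cell)), axis=1)
            count += np.sum(d <= 5.5)
        assert rdf.n_of_r[-1] == pytest.approx(count / n_frames, abs=1e-9)

    def test_single_atom_occupies_single_bin(self):
        cell = [20.0] * 3
        pos = np.array([[10.0, 10.0, 13.3]])
        traj = make_traj([pos], cell)
        rdf = rdf_about_centers(traj, [np.array([[10.0, 10.0, 10.0]])], "O",
                                r_max=5.0, n_bins=25)
        occupied = np.flatnonzero(rdf.g > 0)
        assert len(occupied) == 1
        assert abs(rdf.r[occupied[0]] - 3.3) <= 0.1

    def test_r_max_beyond_half_box_rejected(self):
        traj = make_traj([np.zeros((2, 3))], [8.0] * 3)
        with pytest.raises(GhostMDError):
            rdf_about_centers(traj, [np.zeros((1, 3))], "O", r_max=5.0)

    def test_single_cavity_restriction_skips_twin_frames(self):
        rng = np.random.default_rng(2)
        cell = [12.0] * 3
        frames = rng.uniform(0, 12, size=(4, 50, 3))
        traj = make_traj(frames, cell)
        centers = [np.zeros((1, 3)), np.zeros((2, 3)), None, np.zeros((1, 3))]
        rdf = rdf_about_centers(traj, centers, "O", r_max=5.0,
                                single_cavity_only=True)
        assert rdf.n_frames == 2


class TestCoordination:
    def test_isolated_shell_counts_exactly(self):
        cell = [30.0] * 3
        center = np.full(3, 15.0)
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, 0, -1.0]])
        pos = center + 2.0 * dirs
        traj = make_traj([pos], cell)
        rdf = rdf_about_centers(traj, [center[None]], "O", r_max=6.0,
                                n_bins=60)
        assert coordination_number(rdf, r_cut=3.0) == pytest.approx(4.0)

    def test_ideal_gas_closed_form(self):
        rng = np.random.default_rng(3)
        cell = np.array([12.0] * 3)
        frames = rng.uniform(0, 12, size=(40, 400, 3))
        traj = make_traj(frames, cell)
        centers = [rng.uniform(0, 12, size=(1, 3)) for _ in range(40)]
        rdf = rdf_about_centers(traj, centers, "O", r_max=5.0, n_bins=50)
        rho = 400 / 12.0**3
        r_cut = 4.0
        expect = 4.0 / 3.0 * np.pi * r_cut**3 * rho
        assert coordination_number(rdf, r_cut) == pytest.approx(expect,
                                                                rel=0.05)

    def test_auto_first_minimum_and_failure(self):
        from ghostmd.analysis import RDFResult
        r = np.linspace(0.05, 5.0, 80)
        g = np.exp(-((r - 2.0) / 0.3) ** 2) * 2.5 + \
            np.exp(-((r - 3.8) / 0.4) ** 2) * 1.2
        n = np.cumsum(g)
        rdf = RDFResult(r, g, n, 1, "O")
        r_min_val = coordination_number(rdf, "auto")
        expect = np.interp(r[np.argmin(np.abs(r - 2.9))], r, n)
        assert abs(r_min_val - expect) / expect < 0.2
        flat = RDFResult(r, np.linspace(0, 3, 80), n, 1, "O")
        with pytest.raises(GhostMDError, match="minimum"):
            coordination_number(flat, "auto")


class TestGyration:
    def test_single_point_is_degenerate(self):
        r_gyr, k2 = gyration_stats(np.array([[1.0, 2.0, 3.0]]))
        assert r_gyr == 0.0 and k2 == 0.0

    def test_uniform_sphere_limit(self):
        rng = np.random.default_rng(4)
        R = 2.0
        pts = rng.standard_normal((30000, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= R * rng.uniform(0, 1, 30000)[:, None] ** (1 / 3)
        r_gyr, k2 = gyration_stats(pts)
        assert r_gyr == pytest.approx(np.sqrt(3.0 / 5.0) * R, rel=0.02)
        assert k2 < 0.01

    def test_collinear_points_have_unit_anisotropy(self):
        pts = np.outer(np.linspace(-1, 1, 30), np.array([1.0, 2.0, -0.5]))
        _, k2 = gyration_stats(pts)
        assert k2 == pytest.approx(1.0, abs=1e-12)

    def test_zero_weights_rejected(self):
        with pytest.raises(GhostMDError):
            gyration_stats(np.zeros((3, 3)), np.zeros(3))


class TestMSD:
    def test_fft_equals_direct_quadratic_algorithm(self):
        rng = np.random.default_rng(5)
        track = np.cumsum(rng.standard_normal((200, 3)), axis=0)
        msd_fast = _msd_fft(track)
        msd_direct = np.zeros(len(track))
        for m in range(len(track)):
            d = track[m:] - track[:len(track) - m]
            msd_direct[m] = np.mean(np.sum(d * d, axis=1))
        np.testing.assert_allclose(msd_fast, msd_direct, atol=1e-8)

    def test_ballistic_particle_flagged_as_poor_linear_fit(self):
        t = np.arange(400.0)
        v = np.array([0.03, 0.0, 0.0])
        track = t[:, None] * v
        res = msd_diffusion(track=track, times=t, n_blocks=3)
        np.testing.assert_allclose(res.msd, (np.linalg.norm(v) * t) ** 2,
                                   atol=1e-9)
        assert res.poor_fit

    def test_immobile_particle_has_zero_diffusion(self):
        t = np.arange(300.0)
        res = msd_diffusion(track=np.zeros((300, 3)), times=t)
        assert res.D == 0.0

    def test_short_track_rejected(self):
        with pytest.raises(GhostMDError):
            msd_diffusion(track=np.zeros((6, 3)), times=np.arange(6.0),
                          fit_window=(0.5, 2.0))


class TestShellMembers:
    def _two_in_two_out(self):
        cell = [40.0] * 3
        center = np.full(3, 20.0)
        pos, mol, species = [], [], []
        for m, r in enumerate((2.0, 3.0, 5.0, 7.0)):
            o = center + np.array([r, 0, 0])
            pos += [o, o + [0.5, 0.8, 0], o + [0.5, -0.8, 0]]
            species += ["O", "H", "H"]
            mol += [m] * 3
        return Configuration(species, np.array(pos), cell, mol), center

    def test_inner_molecules_selected(self):
        cfg, center = self._two_in_two_out()
        assert shell_members(cfg, center, r_shell=3.5) == [0, 1]

    def test_default_radius_and_closed_boundary(self):
        cfg, center = self._two_in_two_out()
        import inspect
        assert inspect.signature(shell_members).parameters["r_shell"].default == 3.5
        exact = cfg.copy()
        exact.positions[6] = center + np.array([3.5, 0.0, 0.0])  # O of mol 2
        assert 2 in shell_members(exact, center, r_shell=3.5)


def harmonic_velocity_traj(omega, dt, steps, mass=1.0, amp=1.0, phases=(0.0,)):
    t = np.arange(steps) * dt
    v = np.zeros((steps, len(phases), 3))
    for i, ph in enumerate(phases):
        v[:, i, 0] = amp * omega * np.cos(omega * t + ph)
    pos = np.zeros_like(v)
    return make_traj(pos, [100.0] * 3, times=t, velocities=v,
                     masses=np.full(len(phases), mass))


class TestVDOS:
    def test_harmonic_peak_at_omega_within_one_grid_step(self):
        omega = 0.35  # rad/fs → ~1858 cm⁻¹
        traj = harmonic_velocity_traj(omega, 1.0, 4096)
        spec = vdos(traj)
        grid = spec.nu[1] - spec.nu[0]
        expect = omega / (2 * np.pi) / C_CM_FS
        peak = spec.nu[np.argmax(spec.intensity)]
        assert abs(peak - expect) <= grid

    def test_two_oscillators_intensity_ratio_tracks_energy(self):
        o1, o2 = 0.25, 0.55
        t = np.arange(4096) * 1.0
        v = np.zeros((4096, 2, 3))
        v[:, 0, 0] = 1.0 * np.cos(o1 * t)         # speed amplitude 1
        v[:, 1, 0] = 2.0 * np.cos(o2 * t + 0.4)   # speed amplitude 2 → 4x energy
        traj = make_traj(np.zeros_like(v), [100.0] * 3, times=t, velocities=v,
                         masses=np.ones(2))
        spec = vdos(traj)
        b1 = (spec.nu > o1 / (2 * np.pi) / C_CM_FS - 120) & \
             (spec.nu < o1 / (2 * np.pi) / C_CM_FS + 120)
        b2 = (spec.nu > o2 / (2 * np.pi) / C_CM_FS - 120) & \
             (spec.nu < o2 / (2 * np.pi) / C_CM_FS + 120)
        ratio = spec.intensity[b2].sum() / spec.intensity[b1].sum()
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(6)
        v = rng.standard_normal((8192, 4, 3))
        traj = make_traj(np.zeros_like(v), [100.0] * 3,
                         times=np.arange(8192.0), velocities=v,
                         masses=np.ones(4))
        spec = vdos(traj)
        third = len(spec.nu) // 3
        low = spec.intensity[1:third].mean()
        high = spec.intensity[-third:].mean()
        assert abs(low - high) / low < 0.1

    def test_parseval_identity(self):
        traj = harmonic_velocity_traj(0.4, 1.0, 2048, mass=2.5)
        spec = vdos(traj)
        dnu = spec.nu[1] - spec.nu[0]
        integral = spec.intensity.sum() * dnu
        assert abs(integral - spec.windowed_variance) / spec.windowed_variance \
            < 1e-6

    def test_nyquist_guard(self):
        traj = harmonic_velocity_traj(0.3, 10.0, 256)   # 10 fs stride
        with pytest.raises(GhostMDError, match="Nyquist"):
            vdos(traj)


class TestPeakMetrics:
    def _gauss_spectrum(self, centers, widths, heights):
        nu = np.linspace(800, 2400, 801)
        I = np.zeros_like(nu)
        for c, w, h in zip(centers, widths, heights):
            I += h * np.exp(-((nu - c) / w) ** 2)
        return Spectrum(nu, I, "synthetic")

    def test_single_gaussian_peak_position(self):
        spec = self._gauss_spectrum([1640.0], [40.0], [1.0])
        m = peak_metrics(spec, dict(bend=(1400, 1900)))["bend"]
        grid = spec.nu[1] - spec.nu[0]
        assert abs(m["peak"] - 1640.0) <= grid / 2
        # high-side half maximum of a Gaussian: c + w√(ln 2)
        assert m["half_max"] == pytest.approx(1640 + 40 * np.sqrt(np.log(2)),
                                              abs=grid)

    def test_doublet_resolved_at_60_wavenumber_splitting(self):
        spec = self._gauss_spectrum([1338.0, 1398.0], [18.0, 18.0], [1.0, 0.8])
        m = peak_metrics(spec, dict(bend=(1200, 1500)))["bend"]
        grid = spec.nu[1] - spec.nu[0]
        assert len(m["doublet"]) == 2
        assert m["splitting"] == pytest.approx(60.0, abs=2 * grid)

    def test_self_reference_shift_is_zero(self):
        spec = self._gauss_spectrum([1640.0], [40.0], [1.0])
        m = peak_metrics(spec, dict(bend=(1400, 1900)), reference=spec)["bend"]
        assert m["shift"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_band_reported_absent(self):
        spec = self._gauss_spectrum([1640.0], [40.0], [1.0])
        m = peak_metrics(spec, dict(uv=(3000, 4000)))["uv"]
        assert m["peak"] is None


class TestHydrogenBonds:
    def _dimer(self, d_oo, angle_deg=0.0):
        """Donor molecule at origin donating along +x to an acceptor."""
        cell = [40.0] * 3
        o1 = np.full(3, 20.0)
        th = np.radians(angle_deg)
        h_dir = np.array([np.cos(th), np.sin(th), 0.0])
        pos = [o1, o1 + 0.96 * h_dir, o1 + [-0.3, -0.9, 0.0],
               o1 + [d_oo, 0, 0], o1 + [d_oo + 0.7, 0.7, 0],
               o1 + [d_oo + 0.7, -0.7, 0]]
        return Configuration(["O", "H", "H"] * 2, np.array(pos), cell,
                             [0, 0, 0, 1, 1, 1])

    def test_ideal_linear_bond_saturates(self):
        rep = hb_state(self._dimer(2.6, 0.0))
        assert rep.donor_counts[0] > 0.95
        assert rep.acceptor_counts[1] > 0.95
        assert rep.n_single_donor >= 1

    def test_far_pair_has_no_bond(self):
        rep = hb_state(self._dimer(8.0, 0.0))
        assert rep.donor_counts.max() < 1e-3

    def test_bent_geometry_suppressed(self):
        rep = hb_state(self._dimer(2.6, 60.0))
        assert rep.donor_counts[0] < 0.05

    def test_three_molecule_cluster_matches_independent_formula(self):
        cfg = self._dimer(2.8, 10.0)
        # add a third molecule accepting from molecule 1
        o3 = cfg.positions[3] + np.array([0.2, 2.7, 0.0])
        extra = np.array([o3, o3 + [0.7, 0.7, 0], o3 + [-0.7, 0.7, 0]])
        cfg2 = Configuration(list(cfg.species) + ["O", "H", "H"],
                             np.vstack([cfg.positions, extra]),
                             cfg.cell, list(cfg.molecule_index) + [2, 2, 2])
        params = HBParams()
        rep = hb_state(cfg2, params)

        def logistic(x):
            return 1.0 / (1.0 + np.exp(-x))

        expect_d = np.zeros(3)
        expect_a = np.zeros(3)
        o_idx = [0, 3, 6]
        for m in range(3):
            for h_off in (1, 2):
                h = o_idx[m] + h_off
                for a in range(3):
                    if a == m:
                        continue
                    oa = cfg2.positions[o_idx[a]] - cfg2.positions[o_idx[m]]
                    r = np.linalg.norm(oa)
                    oh = cfg2.positions[h] - cfg2.positions[o_idx[m]]
                    beta = np.degrees(np.arccos(
                        np.dot(oh, oa) / (np.linalg.norm(oh) * r)))
                    p = logistic((params.d0 - r) / params.delta_d) * \
                        logistic((params.theta0 - beta) / params.delta_theta)
                    expect_d[m] += p
                    expect_a[a] += p
        np.testing.assert_allclose(rep.donor_counts, expect_d, atol=1e-10)
        np.testing.assert_allclose(rep.acceptor_counts, expect_a, atol=1e-10)

    def test_difference_report(self):
        a = hb_state(self._dimer(2.6, 0.0))
        b = hb_state(self._dimer(8.0, 0.0))
        d = a.diff(b)
        assert d["single_donor"] >= 1
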