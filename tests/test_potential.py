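"""Neural-network potential: symmetries, analytic gradients, training."""

import copy

import numpy as np
import pytest

from ghostmd.descriptors import SymmetryFunctionSet
from ghostmd.potential import (BPNNModel, ConcentrationWarning,
                               NNPotentialModel, _init_net, _PARAM_KEYS,
                               train_model, validate_model)
from ghostmd.system import GhostMDError
from ghostmd.toy import (Dataset, ToyModelParams, build_box, toy_energy_forces)


@pytest.fixture(scope="module")
def random_model(tiny_sfset, tiny_dataset):
    """Untrained (random-weight) model with sane normalization."""
    est = BPNNModel(tiny_dataset, symmetry_set=tiny_sfset, hidden=(6, 5))
    pre = est._precompute()
    rng = np.random.default_rng(1)
    nets = {e: _init_net(rng, tiny_sfset.n_descriptors, 6, 5)
            for e in tiny_sfset.elements}
    mean, std, offs = {}, {}, {}
    for ei, e in enumerate(tiny_sfset.elements):
        feats = pre.G[:, pre.elem_idx == ei, :].reshape(-1, pre.G.shape[-1])
        mean[e] = feats.mean(0)
        s = feats.std(0)
        std[e] = np.where(s < 1e-8, 1.0, s)
        offs[e] = float(pre.E.mean() / pre.n_atoms)
    return NNPotentialModel(tiny_sfset, nets, mean, std, offs,
                            dict(n_molecules_train=8))


class TestEnergyAndForces:
    def test_energy_invariant_under_molecule_permutation(self, random_model,
                                                         jittered_box):
        e0 = random_model.energy(jittered_box)
        perm = jittered_box.copy()
        # exchange the coordinates of molecules 0 and 1 (same species layout)
        perm.positions[[0, 1, 2, 3, 4, 5]] = perm.positions[[3, 4, 5, 0, 1, 2]]
        assert random_model.energy(perm) == pytest.approx(e0, abs=1e-12)

    def test_energy_at_training_mean_equals_offsets_plus_net_zero(
            self, random_model, tiny_sfset):
        """Feeding the normalization mean gives x = 0 per atom, so the energy
        is Σ (offset + NN(0)) by the z-scoring definition."""
        for elem in tiny_sfset.elements:
            net = random_model.nets[elem]
            e, _ = random_model._atom_energies_and_wG(
                random_model.feat_mean[elem][None, :],
                np.array([list(tiny_sfset.elements).index(elem)]), False)
            h1 = np.tanh(net["b1"])
            h2 = np.tanh(net["W2"] @ h1 + net["b2"])
            nn0 = float(net["w3"] @ h2 + net["b3"])
            assert e[0] == pytest.approx(
                nn0 + random_model.offsets[elem], abs=1e-12)

    def test_forces_match_central_differences(self, random_model,
                                              jittered_box):
        _, F = random_model.energy_forces(jittered_box)
        rng = np.random.default_rng(0)
        h = 1e-5
        for atom in rng.choice(jittered_box.n_atoms, size=3, replace=False):
            for comp in range(3):
                cp = jittered_box.copy()
                cp.positions[atom, comp] += h
                cm = jittered_box.copy()
                cm.positions[atom, comp] -= h
                fd = -(random_model.energy(cp) - random_model.energy(cm)) / (2 * h)
                assert abs(fd - F[atom, comp]) < 1e-5

    def test_net_force_vanishes(self, random_model, jittered_box):
        _, F = random_model.energy_forces(jittered_box)
        assert np.abs(F.sum(axis=0)).max() < 1e-8

    def test_forces_rotate_with_the_configuration(self, random_model,
                                                  tiny_sfset):
        from ghostmd.system import Configuration
        pos = np.array([[0.0, 0, 0], [0.96, 0, 0], [-0.3, 0.9, 0]]) + 45.0
        cfg = Configuration(["O", "H", "H"], pos, [90.0] * 3, [0, 0, 0])
        _, F0 = random_model.energy_forces(cfg)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        rot = cfg.copy()
        com = pos.mean(axis=0)
        rot.positions = (pos - com) @ R.T + com
        _, F1 = random_model.energy_forces(rot)
        np.testing.assert_allclose(F1, F0 @ R.T, atol=1e-9)

    def test_unseen_element_rejected(self, random_model, jittered_box):
        bad = jittered_box.copy()
        bad.species = bad.species.copy()
        bad.species[0] = "N"
        with pytest.raises(GhostMDError):
            random_model.energy(bad)


class TestTrainingGradient:
    def test_loss_gradient_matches_finite_differences(self, tiny_dataset,
                                                      tiny_sfset):
        """Full gradient (energy backprop + force R-op) against central
        differences of the implemented loss."""
        est = BPNNModel(tiny_dataset, symmetry_set=tiny_sfset, hidden=(6, 5),
                        force_weight=0.6)
        pre = est._precompute()
        pre.Jv = pre.Jv.astype(np.float64)
        rng = np.random.default_rng(1)
        nets = {e: _init_net(rng, tiny_sfset.n_descriptors, 6, 5)
                for e in tiny_sfset.elements}
        mean, std, offs = {}, {}, {}
        for ei, e in enumerate(tiny_sfset.elements):
            feats = pre.G[:, pre.elem_idx == ei, :].reshape(-1, pre.G.shape[-1])
            mean[e] = feats.mean(0)
            s = feats.std(0)
            std[e] = np.where(s < 1e-8, 1.0, s)
            offs[e] = float(pre.E.mean() / pre.n_atoms)
        frames = np.arange(len(tiny_dataset))
        _, _, _, grads = est._batch_loss_grad(nets, mean, std, offs, pre,
                                              frames, 0.6)
        h = 2e-6
        rng2 = np.random.default_rng(5)
        for e in tiny_sfset.elements:
            for k in _PARAM_KEYS:
                arr = nets[e][k]
                picks = ([None] if isinstance(arr, float) else
                         [tuple(np.unravel_index(i, arr.shape)) for i in
                          rng2.choice(arr.size, size=min(4, arr.size),
                                      replace=False)])
                for ix in picks:
                    pert = copy.deepcopy(nets)
                    if ix is None:
                        pert[e][k] = arr + h
                    else:
                        pert[e][k] = arr.copy()
                        pert[e][k][ix] += h
                    lp = est._batch_loss_grad(pert, mean, std, offs, pre,
                                              frames, 0.6, want_grad=False)[0]
                    if ix is None:
                        pert[e][k] = arr - h
                    else:
                        pert[e][k][ix] -= 2 * h
                    lm = est._batch_loss_grad(pert, mean, std, offs, pre,
                                              frames, 0.6, want_grad=False)[0]
                    fd = (lp - lm) / (2 * h)
                    an = grads[e][k] if ix is None else grads[e][k][ix]
                    assert abs(fd - an) < 1e-7


@pytest.fixture(scope="module")
def harmonic_molecule_dataset():
    """Labeled samples of a single molecule jittered around its minimum:
    a purely harmonic, easily learnable target."""
    p = ToyModelParams()
    base = build_box(1, cell=[40.0] * 3, seed=0, params=p)
    rng = np.random.default_rng(7)
    samples = []
    for _ in range(150):
        cfg = base.copy()
        cfg.positions = cfg.positions + 0.05 * rng.standard_normal((3, 3))
        samples.append(toy_energy_forces(cfg, p))
    return Dataset(samples, has_ghost=False, metadata=dict(n_molecules=1))


class TestTraining:
    def test_learns_harmonic_molecule_forces(self, harmonic_molecule_dataset):
        sf = SymmetryFunctionSet(r_cut=3.0, r_cut_angular=3.0)
        model, report = train_model(
            harmonic_molecule_dataset,
            hyper=dict(symmetry_set=sf, hidden=(32, 32), epochs=4000,
                       force_weight=0.95, lr=0.006, lr_min=1e-6,
                       batch_size=30), seed=0)
        assert report.force_rmse < 5e-3   # 5 meV/Å

    def test_force_weight_changes_the_fit(self, tiny_dataset, tiny_sfset):
        fits = []
        for w in (0.0, 0.5):
            est = BPNNModel(tiny_dataset, symmetry_set=tiny_sfset,
                            hidden=(4, 4), force_weight=w)
            fits.append(est.fit(seed=3, epochs=4, val_fraction=0.0))
        w1 = fits[0].model.nets["H"]["W1"]
        w2 = fits[1].model.nets["H"]["W1"]
        assert not np.allclose(w1, w2)

    def test_duplicated_data_full_batch_gives_identical_model(
            self, tiny_dataset, tiny_sfset):
        doubled = Dataset(tiny_dataset.samples * 2, has_ghost=False,
                          metadata=dict(tiny_dataset.metadata))
        kw = dict(seed=2, epochs=4, batch_size=None, val_fraction=0.0)
        fit1 = BPNNModel(tiny_dataset, symmetry_set=tiny_sfset,
                         hidden=(4, 4)).fit(**kw)
        fit2 = BPNNModel(doubled, symmetry_set=tiny_sfset,
                         hidden=(4, 4)).fit(**kw)
        for e in tiny_sfset.elements:
            for k in _PARAM_KEYS:
                np.testing.assert_allclose(fit1.model.nets[e][k],
                                           fit2.model.nets[e][k], atol=1e-12)

    def test_deterministic_for_fixed_seed(self, tiny_dataset, tiny_sfset):
        kw = dict(seed=5, epochs=3)
        f1 = BPNNModel(tiny_dataset, symmetry_set=tiny_sfset, hidden=(4, 4)).fit(**kw)
        f2 = BPNNModel(tiny_dataset, symmetry_set=tiny_sfset, hidden=(4, 4)).fit(**kw)
        np.testing.assert_array_equal(f1.model.nets["O"]["W2"],
                                      f2.model.nets["O"]["W2"])

    def test_summary_mentions_errors(self, tiny_dataset, tiny_sfset):
        fit = BPNNModel(tiny_dataset, symmetry_set=tiny_sfset,
                        hidden=(4, 4)).fit(seed=0, epochs=2)
        s = fit.summary()
        assert "force" in s.lower() and "epochs" in s.lower()


class TestValidation:
    def test_constant_model_energy_rmse_equals_label_std(self, tiny_dataset,
                                                         tiny_sfset):
        """A model predicting the mean energy has per-atom energy RMSE equal
        to the (population) std of the per-atom labels — closed form."""
        zero_nets = {}
        for e in tiny_sfset.elements:
            zero_nets[e] = dict(
                W1=np.zeros((4, tiny_sfset.n_descriptors)), b1=np.zeros(4),
                W2=np.zeros((4, 4)), b2=np.zeros(4), w3=np.zeros(4), b3=0.0,
                lin=np.zeros(tiny_sfset.n_descriptors))
        n_at = tiny_dataset.configurations[0].n_atoms
        e0 = float(tiny_dataset.energies.mean()) / n_at
        d = tiny_sfset.n_descriptors
        model = NNPotentialModel(
            tiny_sfset, zero_nets,
            {e: np.zeros(d) for e in tiny_sfset.elements},
            {e: np.ones(d) for e in tiny_sfset.elements},
            {e: e0 for e in tiny_sfset.elements},
            dict(has_ghost=False))
        report = validate_model(model, tiny_dataset)
        expected = float(np.std(tiny_dataset.energies / n_at))
        assert report.energy_rmse_per_atom == pytest.approx(expected, rel=1e-9)

    def test_identical_subsets_report_identical_rmse(self, tiny_dataset,
                                                     tiny_sfset):
        fit = BPNNModel(tiny_dataset, symmetry_set=tiny_sfset,
                        hidden=(4, 4)).fit(seed=0, epochs=2)
        labels = ["a", "b"] * (len(tiny_dataset) // 2)
        rep = validate_model(fit.model, tiny_dataset, subsets=labels)
        # the two interleaved subsets see the same frames only on average;
        # but a subset equal to the whole set must reproduce the global RMSE
        rep_all = validate_model(fit.model, tiny_dataset,
                                 subsets=["all"] * len(tiny_dataset))
        assert rep_all.subsets["all"]["e"] == pytest.approx(
            rep_all.energy_rmse_per_atom)
        assert set(rep.subsets) == {"a", "b"}

    def test_mismatched_ghost_label_rejected(self, tiny_dataset, tiny_sfset):
        fit = BPNNModel(tiny_dataset, symmetry_set=tiny_sfset,
                        hidden=(4, 4)).fit(seed=0, epochs=2)
        fit.model.metadata["has_ghost"] = True
        with pytest.raises(GhostMDError):
            validate_model(fit.model, tiny_dataset)


class TestModelIO:
    def test_hdf5_round_trip_preserves_predictions(self, tiny_dataset,
                                                   tiny_sfset, jittered_box,
                                                   tmp_path):
        fit = BPNNModel(tiny_dataset, symmetry_set=tiny_sfset,
                        hidden=(4, 4)).fit(seed=0, epochs=2)
        path = tmp_path / "model.h5"
        fit.save(path)
        loaded = NNPotentialModel.load(path)
        assert loaded.energy(jittered_box) == pytest.approx(
            fit.model.energy(jittered_box), abs=1e-12)
        F0 = fit.model.forces(jittered_box)
        np.testing.assert_allclose(loaded.forces(jittered_box), F0, atol=1e-12)

    def test_size_transfer_emits_concentration_warning(self, random_model):
        other = build_box(2, cell=[30.0] * 3, seed=0)
        with pytest.warns(ConcentrationWarning):
            random_model.bind(other)
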