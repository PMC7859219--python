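"""Ghost-free neural-network potential: per-element networks over symmetry functions.

The total energy is a sum of atomic contributions,
E = Σ_i [ off_e(i) + NN_e(i)( (G_i − μ_e)/σ_e ) ],
with one two-hidden-layer tanh network per element and per-feature z-scoring
from the training split.  Forces are the exact analytic gradient of this
energy (chain rule through the network and the descriptor Jacobian) — the
backward pass is hand-coded, so what the integrator sees is the derivative
of the implemented energy to machine precision, not an autodiff approximation
of a different graph.

Training minimizes L = (1−w)·MSE(E/atom) + w·MSE(F).  The gradient of the
force term with respect to the weights is a Hessian-vector product through
the network; it is assembled with a forward (R-operator) tangent pass in the
direction set by the force residuals, followed by a reverse pass over the
combined graph.

``BPNNModel`` / ``BPNNFit`` expose the estimator in model/results style;
``train_model`` and ``validate_model`` are thin functional wrappers.

A trained potential is concentration-specific: the ghost's presence is an
implicit parameter of its training data, so running it at a different
molecule count changes the physical meaning of the model.  Binding a model
to a config of a different size emits a loud warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .descriptors import SparseJacobian, SymmetryFunctionSet, symmetry_vectors
from .system import Configuration, GhostMDError
from .toy import Dataset

logger = logging.getLogger(__name__)

_PARAM_KEYS = ("W1", "b1", "W2", "b2", "w3", "b3", "lin")


class ConcentrationWarning(UserWarning):
    """Model evaluated at a system size it was not trained for."""


# ---------------------------------------------------------------------------
# numba contraction kernels (shared by force evaluation and training)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _contract_forces(atoms, values, counts, w, F_out):
    """F_out[a] -= Σ_{i,s→a} Σ_d w[i,d]·values[i,s,d,:] (one frame)."""
    N, ndesc = w.shape
    for i in range(N):
        for s in range(counts[i]):
            a = atoms[i, s]
            fx = 0.0
            fy = 0.0
            fz = 0.0
            for d in range(ndesc):
                wd = w[i, d]
                fx += wd * values[i, s, d, 0]
                fy += wd * values[i, s, d, 1]
                fz += wd * values[i, s, d, 2]
            F_out[a, 0] -= fx
            F_out[a, 1] -= fy
            F_out[a, 2] -= fz


@njit(cache=True)
def _gather_tangent(atoms, values, counts, cF, v_out):
    """v_out[i,d] = −Σ_s values[i,s,d,:]·cF[atoms[i,s],:]  (∂L/∂(dE/dG))."""
    N, ndesc = v_out.shape
    for i in range(N):
        for s in range(counts[i]):
            a = atoms[i, s]
            cx = cF[a, 0]
            cy = cF[a, 1]
            cz = cF[a, 2]
            for d in range(ndesc):
                v_out[i, d] -= (values[i, s, d, 0] * cx +
                                values[i, s, d, 1] * cy +
                                values[i, s, d, 2] * cz)


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class ErrorReport:
    """Held-out (or requested-set) error summary."""

    energy_rmse_per_atom: float     # eV/atom
    force_rmse: float               # eV/Å
    n_samples: int
    subsets: dict = field(default_factory=dict)   # label -> dict(e, f, n)

    def __str__(self) -> str:
        lines = [f"energy RMSE : {self.energy_rmse_per_atom * 1e3:9.4f} meV/atom",
                 f"force RMSE  : {self.force_rmse * 1e3:9.4f} meV/Å",
                 f"samples     : {self.n_samples}"]
        for label, d in self.subsets.items():
            lines.append(f"  [{label}] energy {d['e'] * 1e3:.4f} meV/atom, "
                         f"force {d['f'] * 1e3:.4f} meV/Å (n={d['n']})")
        return "\n".join(lines)


class NNPotentialModel:
    """Trained per-element networks + normalization + metadata."""

    def __init__(self, sfset: SymmetryFunctionSet, nets: dict,
                 feat_mean: dict, feat_std: dict, offsets: dict,
                 metadata: dict | None = None):
        self.sfset = sfset
        self.nets = nets              # elem -> {W1,b1,W2,b2,w3,b3}
        self.feat_mean = feat_mean    # elem -> (ndesc,)
        self.feat_std = feat_std
        self.offsets = offsets        # elem -> float (eV/atom)
        self.metadata = metadata or {}

    @property
    def elements(self):
        return self.sfset.elements

    # -- fast paths on precomputed descriptors -------------------------
    def _atom_energies_and_wG(self, G: np.ndarray, elem_idx: np.ndarray,
                              want_grad: bool):
        """Per-atom energies e_i and (optionally) dE/dG_i."""
        N = len(G)
        e = np.empty(N)
        wG = np.empty_like(G) if want_grad else None
        for ei, elem in enumerate(self.elements):
            mask = elem_idx == ei
            if not mask.any():
                continue
            net = self.nets[elem]
            X = (G[mask] - self.feat_mean[elem]) / self.feat_std[elem]
            Z1 = X @ net["W1"].T + net["b1"]
            H1 = np.tanh(Z1)
            Z2 = H1 @ net["W2"].T + net["b2"]
            H2 = np.tanh(Z2)
            e[mask] = (H2 @ net["w3"] + net["b3"] + X @ net["lin"]
                       + self.offsets[elem])
            if want_grad:
                gx = (((1.0 - H2 * H2) * net["w3"]) @ net["W2"]
                      * (1.0 - H1 * H1)) @ net["W1"] + net["lin"]
                wG[mask] = gx / self.feat_std[elem]
        return e, wG

    def energy_forces(self, config: Configuration):
        """Total energy (eV) and analytic forces (eV/Å) for one configuration."""
        G, J = symmetry_vectors(config, self.sfset, want_jacobian=True)
        elem_idx = self.sfset.element_index(config.elements)
        e, wG = self._atom_energies_and_wG(G, elem_idx, want_grad=True)
        F = np.zeros((len(G), 3))
        _contract_forces(J.atoms, J.values, J.counts, wG, F)
        return float(e.sum()), F

    def energy(self, config: Configuration) -> float:
        G, _ = symmetry_vectors(config, self.sfset, want_jacobian=False)
        elem_idx = self.sfset.element_index(config.elements)
        e, _ = self._atom_energies_and_wG(G, elem_idx, want_grad=False)
        return float(e.sum())

    def forces(self, config: Configuration) -> np.ndarray:
        return self.energy_forces(config)[1]

    def bind(self, config: Configuration) -> "BoundNNPotential":
        return BoundNNPotential(self, config)

    # -- serialization -------------------------------------------------
    def save(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = 1
            f.attrs["symmetry_set"] = json.dumps(self.sfset.to_dict())
            f.attrs["metadata"] = json.dumps(self.metadata, default=float)
            for elem in self.elements:
                g = f.create_group(f"element/{elem}")
                for k in _PARAM_KEYS:
                    g.create_dataset(k, data=np.atleast_1d(self.nets[elem][k]))
                g.create_dataset("feat_mean", data=self.feat_mean[elem])
                g.create_dataset("feat_std", data=self.feat_std[elem])
                g.attrs["offset"] = self.offsets[elem]

    @classmethod
    def load(cls, path) -> "NNPotentialModel":
        import h5py
        with h5py.File(path, "r") as f:
            sfset = SymmetryFunctionSet.from_dict(
                json.loads(f.attrs["symmetry_set"]))
            metadata = json.loads(f.attrs["metadata"])
            nets, mean, std, off = {}, {}, {}, {}
            for elem in sfset.elements:
                g = f[f"element/{elem}"]
                net = {k: np.array(g[k]) for k in _PARAM_KEYS}
                net["b3"] = float(net["b3"][0])
                nets[elem] = net
                mean[elem] = np.array(g["feat_mean"])
                std[elem] = np.array(g["feat_std"])
                off[elem] = float(g.attrs["offset"])
        return cls(sfset, nets, mean, std, off, metadata)


class BoundNNPotential:
    """Model fixed to one composition/cell, callable by the MD engines."""

    def __init__(self, model: NNPotentialModel, config: Configuration):
        self.model = model
        self.species = config.species
        self.cell = config.cell
        self.molecule_index = config.molecule_index
        self.elem_idx = model.sfset.element_index(config.elements)
        self.n_atoms = config.n_atoms
        trained_n = model.metadata.get("n_molecules_train")
        if trained_n is not None and trained_n != config.n_molecules:
            warnings.warn(
                f"model was trained on {trained_n} molecules but is being run "
                f"on {config.n_molecules}: the potential is effectively trained "
                "at a fixed solute concentration and transferring it across "
                "system sizes changes the physics it encodes",
                ConcentrationWarning, stacklevel=2)
        self.max_frequency = model.metadata.get("max_frequency")
        self._template = Configuration(config.species, config.positions,
                                       config.cell, config.molecule_index)

    def energy_forces(self, positions: np.ndarray):
        single = positions.ndim == 2
        pos = positions[None] if single else positions
        B = pos.shape[0]
        E = np.empty(B)
        F = np.empty((B, self.n_atoms, 3))
        for b in range(B):
            cfg = self._template.with_positions(pos[b])
            E[b], F[b] = self.model.energy_forces(cfg)
        return (float(E[0]), F[0]) if single else (E, F)


def nn_energy(model: NNPotentialModel, config: Configuration) -> float:
    """Total NN energy of a configuration (eV)."""
    return model.energy(config)


def nn_forces(model: NNPotentialModel, config: Configuration) -> np.ndarray:
    """Analytic NN forces, F = −∂E/∂R (eV/Å)."""
    return model.forces(config)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _init_net(rng: np.random.Generator, d: int, h1: int, h2: int) -> dict:
    """Random tanh network plus a zero-initialized linear bypass.

    The linear term e_lin = lin·x lets energy scales that are (near-)linear
    in the descriptors — notably the large energetic separation between
    cavity and collapsed states — be represented directly instead of through
    saturating units; it is warm-started by ridge regression in fit()."""
    return dict(
        W1=rng.normal(0.0, 1.0 / np.sqrt(d), size=(h1, d)),
        b1=np.zeros(h1),
        W2=rng.normal(0.0, 1.0 / np.sqrt(h1), size=(h2, h1)),
        b2=np.zeros(h2),
        w3=rng.normal(0.0, 0.1 / np.sqrt(h2), size=h2),
        b3=0.0,
        lin=np.zeros(d),
    )


def _zeros_like_net(net: dict) -> dict:
    return {k: (np.zeros_like(v) if isinstance(v, np.ndarray) else 0.0)
            for k, v in net.items()}


class _Precomputed:
    """Descriptors + sparse Jacobians for a whole dataset, padded uniformly."""

    def __init__(self, dataset: Dataset, sfset: SymmetryFunctionSet):
        configs = dataset.configurations
        n_frames = len(configs)
        self.elem_idx = sfset.element_index(configs[0].elements)
        self.n_atoms = configs[0].n_atoms
        # store Jacobians in float32 as they are produced (memory: the padded
        # array for ~1000 frames of ~100 atoms is ~1.4 GB; float64 would not fit
        # comfortably next to the training workspace)
        Gs, Jvals, Jatoms, Jcounts = [], [], [], []
        for cfg in configs:
            G, J = symmetry_vectors(cfg, sfset, want_jacobian=True)
            Gs.append(G)
            Jvals.append(J.values.astype(np.float32))
            Jatoms.append(J.atoms)
            Jcounts.append(J.counts)
        self.G = np.stack(Gs)                                   # (F,N,nd)
        S = max(int(c.max()) for c in Jcounts)
        nd = self.G.shape[2]
        self.Jv = np.zeros((n_frames, self.n_atoms, S, nd, 3), dtype=np.float32)
        self.Ja = np.zeros((n_frames, self.n_atoms, S), dtype=np.int64)
        self.Jc = np.zeros((n_frames, self.n_atoms), dtype=np.int64)
        for f in range(n_frames):
            s = min(S, Jvals[f].shape[1])
            self.Jv[f, :, :s] = Jvals[f][:, :s]
            self.Ja[f, :, :s] = Jatoms[f][:, :s]
            self.Jc[f] = Jcounts[f]
        del Jvals
        self.E = dataset.energies
        self.F = dataset.forces


@dataclass
class TrainingOptions:
    hidden: tuple[int, int] = (24, 24)
    epochs: int = 120
    lr: float = 0.01
    lr_min: float = 5e-4
    force_weight: float = 0.5
    batch_size: int | None = 32
    val_fraction: float = 0.1
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    #: per-frame-label multipliers for the force term; frames whose reference
    #: forces are unreliable (e.g. homogeneous frames labeled on a multi-basin
    #: ghost surface) can be supervised through their energies only (weight 0)
    force_weights_by_label: dict | None = None
    #: per-frame-label multipliers for the energy term; lets rare but
    #: physically decisive strata (the cavity-collapse penalty) pull their
    #: weight against the majority class
    energy_weights_by_label: dict | None = None


class BPNNModel:
    """Estimator for a ghost-free potential on a labeled dataset.

    Statsmodels-style: construct from data, call :meth:`fit`, inspect the
    returned :class:`BPNNFit`.
    """

    def __init__(self, dataset: Dataset,
                 symmetry_set: SymmetryFunctionSet | None = None,
                 hidden: tuple[int, int] = (24, 24),
                 force_weight: float = 0.5):
        if len(dataset) < 2:
            raise GhostMDError("need at least 2 samples")
        self.dataset = dataset
        self.sfset = symmetry_set or SymmetryFunctionSet()
        self.hidden = hidden
        self.force_weight = force_weight
        self._pre: _Precomputed | None = None

    def _precompute(self) -> _Precomputed:
        if self._pre is None:
            logger.info("precomputing descriptors for %d frames", len(self.dataset))
            self._pre = _Precomputed(self.dataset, self.sfset)
        return self._pre

    def _split(self, seed: int, val_fraction: float):
        """Stratified train/validation split over frame labels (if any)."""
        n = len(self.dataset)
        rng = np.random.default_rng(seed)
        labels = self.dataset.frame_labels or ["all"] * n
        train_idx, val_idx = [], []
        for lab in sorted(set(labels)):
            idx = np.array([i for i, l in enumerate(labels) if l == lab])
            rng.shuffle(idx)
            n_val = max(1, int(round(val_fraction * len(idx)))) \
                if len(idx) > 1 and val_fraction > 0 else 0
            val_idx.extend(idx[:n_val])
            train_idx.extend(idx[n_val:])
        return np.sort(train_idx), np.sort(val_idx)

    # -- loss and gradient on a batch of frames ------------------------
    def _batch_loss_grad(self, nets, mean, std, offsets, pre, frames,
                         w_force, want_grad=True, frame_force_w=None,
                         frame_energy_w=None):
        elem_idx = pre.elem_idx
        N = pre.n_atoms
        B = len(frames)
        G = pre.G[frames]
        E_ref = pre.E[frames]
        F_ref = pre.F[frames]
        fw = (np.ones(B) if frame_force_w is None
              else np.asarray(frame_force_w, float)[frames])
        fw_total = max(fw.sum(), 1e-12)
        ew = (np.ones(B) if frame_energy_w is None
              else np.asarray(frame_energy_w, float)[frames])
        ew_total = max(ew.sum(), 1e-12)
        grads = {e: _zeros_like_net(nets[e]) for e in nets} if want_grad else None

        # normalized inputs, stacked per element over (frame, atom)
        X, fwd = {}, {}
        for ei, elem in enumerate(self.sfset.elements):
            mask = elem_idx == ei
            if not mask.any():
                continue
            Xe = (G[:, mask, :] - mean[elem]) / std[elem]
            Xe = Xe.reshape(-1, Xe.shape[-1])
            net = nets[elem]
            Z1 = Xe @ net["W1"].T + net["b1"]
            H1 = np.tanh(Z1)
            Z2 = H1 @ net["W2"].T + net["b2"]
            H2 = np.tanh(Z2)
            e_at = H2 @ net["w3"] + net["b3"] + Xe @ net["lin"] + offsets[elem]
            X[elem] = Xe
            fwd[elem] = (mask, H1, H2, e_at)

        # assemble per-atom energies and dE/dG
        e_atoms = np.empty((B, N))
        wG = np.empty((B, N, G.shape[-1]))
        for elem, (mask, H1, H2, e_at) in fwd.items():
            ne = int(mask.sum())
            e_atoms[:, mask] = e_at.reshape(B, ne)
            net = nets[elem]
            gx = (((1.0 - H2 * H2) * net["w3"]) @ net["W2"]
                  * (1.0 - H1 * H1)) @ net["W1"] + net["lin"]
            wG[:, mask, :] = (gx / std[elem]).reshape(B, ne, -1)

        E_pred = e_atoms.sum(axis=1)
        dE = E_pred - E_ref
        loss_e = float(np.sum(ew * (dE / N) ** 2) / ew_total)

        F_pred = np.zeros((B, N, 3))
        for b, f in enumerate(frames):
            _contract_forces(pre.Ja[f], pre.Jv[f], pre.Jc[f],
                             wG[b].astype(pre.Jv.dtype), F_pred[b])
        dF = F_pred - F_ref
        loss_f = float(np.sum(fw[:, None, None] * dF * dF) /
                       (fw_total * N * 3))
        loss = (1.0 - w_force) * loss_e + w_force * loss_f
        if not want_grad:
            return loss, loss_e, loss_f, None

        # adjoints
        o_frame = 2.0 * (1.0 - w_force) * ew * dE / (N * N * ew_total)
        cF = (2.0 * w_force / (fw_total * N * 3)) * \
            fw[:, None, None] * dF                                # ∂L/∂F_pred
        V = np.zeros_like(wG)                                     # ∂L/∂(dE/dG)
        for b, f in enumerate(frames):
            _gather_tangent(pre.Ja[f], pre.Jv[f], pre.Jc[f],
                            cF[b].astype(pre.Jv.dtype), V[b])

        for elem, (mask, H1, H2, e_at) in fwd.items():
            net = nets[elem]
            g = grads[elem]
            Xe = X[elem]
            ne = int(mask.sum())
            T1 = 1.0 - H1 * H1
            T2 = 1.0 - H2 * H2
            # --- energy term: plain backprop -------------------------
            o = np.repeat(o_frame, ne)                            # (B*ne,)
            g["w3"] += H2.T @ o
            g["b3"] += float(o.sum())
            g["lin"] += Xe.T @ o
            d2 = o[:, None] * net["w3"] * T2
            g["W2"] += d2.T @ H1
            g["b2"] += d2.sum(axis=0)
            d1 = (d2 @ net["W2"]) * T1
            g["W1"] += d1.T @ Xe
            g["b1"] += d1.sum(axis=0)
            # --- force term: R-op tangent then reverse ---------------
            # tangent direction in normalized-input space
            Ve = (V[:, mask, :].reshape(-1, V.shape[-1])) / std[elem]
            g["lin"] += Ve.sum(axis=0)        # ∂(gx·V)/∂lin = V
            Z1d = Ve @ net["W1"].T
            H1d = T1 * Z1d
            Z2d = H1d @ net["W2"].T
            H2d = T2 * Z2d
            g["w3"] += H2d.sum(axis=0)
            aZ2d = np.broadcast_to(net["w3"], H2.shape) * T2      # ∂φ/∂Ż2
            aZ2 = net["w3"] * Z2d * (-2.0 * H2 * T2)              # via T2(Z2)
            g["W2"] += aZ2d.T @ H1d + aZ2.T @ H1
            g["b2"] += aZ2.sum(axis=0)
            aH1d = aZ2d @ net["W2"]
            aH1 = aZ2 @ net["W2"]
            aZ1d = T1 * aH1d
            aZ1 = aH1d * Z1d * (-2.0 * H1 * T1) + T1 * aH1
            g["W1"] += aZ1d.T @ Ve + aZ1.T @ Xe
            g["b1"] += aZ1.sum(axis=0)
        return loss, loss_e, loss_f, grads

    def fit(self, seed: int = 0, options: TrainingOptions | None = None,
            **kwargs) -> "BPNNFit":
        """Train with Adam; deterministic for a fixed seed.

        Keyword arguments override fields of :class:`TrainingOptions`.
        """
        opts = options or TrainingOptions(hidden=self.hidden,
                                          force_weight=self.force_weight)
        for k, v in kwargs.items():
            if not hasattr(opts, k):
                raise GhostMDError(f"unknown training option {k!r}")
            setattr(opts, k, v)
        pre = self._precompute()
        train_idx, val_idx = self._split(seed, opts.val_fraction)
        rng = np.random.default_rng(seed)

        # normalization and offsets from the training split only
        mean, std, offsets = {}, {}, {}
        Gtr = pre.G[train_idx]
        e0 = float(np.mean(pre.E[train_idx])) / pre.n_atoms
        for ei, elem in enumerate(self.sfset.elements):
            mask = pre.elem_idx == ei
            feats = Gtr[:, mask, :].reshape(-1, Gtr.shape[-1])
            mean[elem] = feats.mean(axis=0)
            s = feats.std(axis=0)
            std[elem] = np.where(s < 1e-8, 1.0, s)
            offsets[elem] = e0

        labels = self.dataset.frame_labels or ["all"] * len(self.dataset)
        frame_force_w = None
        if opts.force_weights_by_label:
            frame_force_w = np.array(
                [float(opts.force_weights_by_label.get(l, 1.0))
                 for l in labels])
        frame_energy_w = None
        if opts.energy_weights_by_label:
            frame_energy_w = np.array(
                [float(opts.energy_weights_by_label.get(l, 1.0))
                 for l in labels])

        d = pre.G.shape[-1]
        h1, h2 = opts.hidden
        nets = {e: _init_net(rng, d, h1, h2) for e in self.sfset.elements}

        # ridge warm start: per-element linear terms on total-energy residuals
        elems_present = [e for i, e in enumerate(self.sfset.elements)
                         if (pre.elem_idx == i).any()]
        feats = []
        for e in elems_present:
            ei = list(self.sfset.elements).index(e)
            mask = pre.elem_idx == ei
            Xsum = ((pre.G[train_idx][:, mask, :] - mean[e]) / std[e]).sum(axis=1)
            feats.append(Xsum)
        A = np.hstack(feats + [np.ones((len(train_idx), 1))])
        y = pre.E[train_idx] - pre.n_atoms * e0
        lam = 1e-3 * len(train_idx)
        reg = lam * np.eye(A.shape[1])
        reg[-1, -1] = 0.0
        coef = np.linalg.solve(A.T @ A + reg, A.T @ y)
        ptr = 0
        for e in elems_present:
            nets[e]["lin"] = coef[ptr:ptr + d].copy()
            ptr += d
        for e in self.sfset.elements:
            offsets[e] = offsets[e] + float(coef[-1]) / pre.n_atoms

        # Adam state
        m_state = {e: _zeros_like_net(nets[e]) for e in nets}
        v_state = {e: _zeros_like_net(nets[e]) for e in nets}
        t_adam = 0
        history = []
        n_train = len(train_idx)
        bs = opts.batch_size or n_train
        for epoch in range(opts.epochs):
            lr = opts.lr_min + 0.5 * (opts.lr - opts.lr_min) * (
                1.0 + np.cos(np.pi * epoch / max(1, opts.epochs - 1)))
            if opts.batch_size is None:
                order = np.asarray(train_idx)
            else:
                order = rng.permutation(train_idx)
            ep_loss = 0.0
            n_batches = 0
            for start in range(0, n_train, bs):
                batch = order[start:start + bs]
                loss, le, lf, grads = self._batch_loss_grad(
                    nets, mean, std, offsets, pre, batch, opts.force_weight,
                    frame_force_w=frame_force_w,
                    frame_energy_w=frame_energy_w)
                if not np.isfinite(loss):
                    raise GhostMDError(
                        f"divergent loss at epoch {epoch}; history={history}")
                t_adam += 1
                bc1 = 1.0 - opts.beta1 ** t_adam
                bc2 = 1.0 - opts.beta2 ** t_adam
                for e in nets:
                    for k in _PARAM_KEYS:
                        gk = grads[e][k]
                        m_state[e][k] = opts.beta1 * m_state[e][k] + \
                            (1 - opts.beta1) * gk
                        v_state[e][k] = opts.beta2 * v_state[e][k] + \
                            (1 - opts.beta2) * (gk * gk if isinstance(gk, np.ndarray)
                                                else gk * gk)
                        step = lr * (m_state[e][k] / bc1) / (
                            np.sqrt(v_state[e][k] / bc2) + opts.adam_eps)
                        nets[e][k] = nets[e][k] - step
                ep_loss += loss
                n_batches += 1
            history.append(ep_loss / n_batches)

        meta = dict(has_ghost=self.dataset.has_ghost,
                    train_seed=seed,
                    loss_history=history,
                    n_molecules_train=self.dataset.metadata.get(
                        "n_molecules",
                        self.dataset.configurations[0].n_molecules),
                    force_weight=opts.force_weight,
                    hidden=list(opts.hidden),
                    epochs=opts.epochs)
        # carry the stiffest toy frequency so MD time-step checks still work
        params = self.dataset.metadata.get("params")
        if params:
            from .units import ATOMIC_MASSES, MASS_EV
            mu = ATOMIC_MASSES["O"] * ATOMIC_MASSES["H"] / (
                ATOMIC_MASSES["O"] + ATOMIC_MASSES["H"])
            meta["max_frequency"] = float(
                np.sqrt(params["k_bond"] / (mu * MASS_EV)))
        model = NNPotentialModel(self.sfset, nets, mean, std, offsets, meta)
        report = self._evaluate(model, pre, val_idx if len(val_idx) else train_idx)
        return BPNNFit(model, report, history, train_idx, val_idx)

    def _evaluate(self, model, pre, idx) -> ErrorReport:
        labels = self.dataset.frame_labels
        de, df, per = [], [], {}
        for f in idx:
            e_at, wG = model._atom_energies_and_wG(pre.G[f], pre.elem_idx, True)
            F = np.zeros((pre.n_atoms, 3))
            _contract_forces(pre.Ja[f], pre.Jv[f], pre.Jc[f],
                             wG.astype(pre.Jv.dtype), F)
            de.append((e_at.sum() - pre.E[f]) / pre.n_atoms)
            df.append(F - pre.F[f])
            if labels:
                per.setdefault(labels[f], []).append((de[-1], df[-1]))
        de = np.array(de)
        df = np.stack(df)
        subsets = {}
        for lab, vals in per.items():
            se = np.array([v[0] for v in vals])
            sf = np.stack([v[1] for v in vals])
            subsets[lab] = dict(e=float(np.sqrt(np.mean(se ** 2))),
                                f=float(np.sqrt(np.mean(sf ** 2))),
                                n=len(vals))
        return ErrorReport(float(np.sqrt(np.mean(de ** 2))),
                           float(np.sqrt(np.mean(df ** 2))),
                           len(idx), subsets)


class BPNNFit:
    """Results of a potential fit: trained model, held-out errors, history."""

    def __init__(self, model: NNPotentialModel, report: ErrorReport,
                 loss_history: list, train_idx, val_idx):
        self.model = model
        self.report = report
        self.loss_history = loss_history
        self.train_idx = train_idx
        self.val_idx = val_idx

    # convenience passthroughs
    def predict_energy(self, config: Configuration) -> float:
        return self.model.energy(config)

    def predict_forces(self, config: Configuration) -> np.ndarray:
        return self.model.forces(config)

    def bind(self, config: Configuration) -> BoundNNPotential:
        return self.model.bind(config)

    def save(self, path) -> None:
        self.model.save(path)

    def summary(self) -> str:
        m = self.model.metadata
        head = [
            "Ghost-free potential fit",
            "=" * 44,
            f"descriptors / atom     : {self.model.sfset.n_descriptors}",
            f"hidden layers          : {m.get('hidden')}",
            f"training frames        : {len(self.train_idx)}",
            f"validation frames      : {len(self.val_idx)}",
            f"epochs                 : {m.get('epochs')}",
            f"force weight w         : {m.get('force_weight')}",
            f"trained with ghost     : {m.get('has_ghost')}",
            f"final training loss    : {self.loss_history[-1]:.3e}",
            "-" * 44,
        ]
        return "\n".join(head) + "\n" + str(self.report)


# ---------------------------------------------------------------------------
# functional wrappers (module surface)
# ---------------------------------------------------------------------------

def train_model(dataset: Dataset, hyper: dict | None = None,
                seed: int = 0) -> tuple[NNPotentialModel, ErrorReport]:
    """Train a ghost-free potential; returns (model, held-out ErrorReport)."""
    hyper = dict(hyper or {})
    sfset = hyper.pop("symmetry_set", None)
    hidden = tuple(hyper.pop("hidden", (24, 24)))
    fw = hyper.pop("force_weight", 0.5)
    est = BPNNModel(dataset, symmetry_set=sfset, hidden=hidden, force_weight=fw)
    fit = est.fit(seed=seed, **hyper)
    return fit.model, fit.report


def validate_model(model: NNPotentialModel, dataset: Dataset,
                   subsets: list[str] | None = None) -> ErrorReport:
    """Energy/force RMSE of a model on a labeled dataset, overall and per subset."""
    if model.metadata.get("has_ghost") is not None and \
            model.metadata["has_ghost"] != dataset.has_ghost:
        raise GhostMDError("dataset has_ghost does not match the model label")
    labels = subsets if subsets is not None else dataset.frame_labels
    de, dfs, per = [], [], {}
    for i, sample in enumerate(dataset.samples):
        E, F = model.energy_forces(sample.configuration)
        n = sample.configuration.n_atoms
        de.append((E - sample.energy) / n)
        dfs.append(F - sample.forces)
        if labels:
            per.setdefault(labels[i], []).append(i)
    de = np.array(de)
    dfs = np.stack(dfs)
    subsets_out = {}
    if labels:
        for lab in sorted(set(labels)):
            idx = per.get(lab, [])
            if not idx:
                continue
            subsets_out[lab] = dict(
                e=float(np.sqrt(np.mean(de[idx] ** 2))),
                f=float(np.sqrt(np.mean(dfs[idx] ** 2))),
                n=len(idx))
    return ErrorReport(float(np.sqrt(np.mean(de ** 2))),
                       float(np.sqrt(np.mean(dfs ** 2))),
                       len(dataset), subsets_out)
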