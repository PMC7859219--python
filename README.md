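# ghostmd

Ghost-particle machine-learning potentials and ring-polymer quantum dynamics
for cavity-forming quasiparticle solutes, at desk scale.

## The problem

Some solutes have no atoms.  An excess electron in water carves a cavity
lined by 4–5 OH groups, diffuses, exchanges isotopes with its shell and
shifts vibrational bands — yet a conventional force field has no site to
put it on, and the electronic-structure methods accurate enough to describe
it are far too expensive for the hundreds of picoseconds that its
statistical mechanics demands.  The "ghost particle" strategy resolves
this: an atom-centered neural-network potential is trained on reference
calculations *with* the solute present, but sees only nuclear coordinates —
the solute's effect lives entirely in the structural correlations of the
surrounding molecules.  The resulting potential is cheap enough for
thermostatted ring-polymer MD (TRPMD), so nuclear quantum effects, isotope
fractionation and vibrational spectra become accessible.

`ghostmd` implements this whole program on a self-contained synthetic
system, so that every stage can be built, trained and *tested* without
external reference data:

- **toy reference** — a flexible 3-site polar fluid plus one explicit ghost
  particle (Gaussian attraction to H sites, steep Gaussian repulsion from O
  sites), adiabatically relaxed for every configuration.  It produces
  labeled energies and Hellmann–Feynman nuclear forces, playing the role of
  the expensive reference method;
- **mlpotential** — Behler–Parrinello symmetry functions (radial G2,
  angular G4) feeding per-element tanh networks with a ridge-initialized
  linear bypass; energy `E = Σ_i E_elem(i)(G_i)`, forces as the exact
  analytic gradient (hand-coded backpropagation, force-loss gradients via
  an R-operator pass).  `BPNNModel(dataset).fit()` returns a `BPNNFit`
  results object with held-out errors, per-stratum cross-validation and a
  `summary()`;
- **dynamics** — one BAOAB integrator for classical MD and TRPMD (exact
  free-ring-polymer normal-mode propagation, PILE thermostat, P = 1
  reduces bit-for-bit to classical Langevin), plus the electron-injection
  protocol (equilibrate with the neat-trained potential, switch to the
  solute-trained one at t = 0, watch the cavity form);
- **isotope_alchemy** — H↔D mass-swap Monte Carlo inside TRPMD
  (`P_acc = min(1, e^{−βΔE_spring})`) and two estimators of the cavity
  fractionation constant `K_eq = (n_H/n_D)_shell / (n_H/n_D)_bulk`;
- **analysis** — maximin-void cavity detection and tracking (twin-cavity
  flags, identity-switch events), cavity-centered RDFs and coordination
  numbers, gyration radius and relative shape anisotropy κ², FFT-based MSD
  diffusion with block errors, mass-weighted VDOS with band peak metrics,
  and a probabilistic hydrogen-bond census;
- **io / cli** — extended-XYZ (bit-identical round trips) and HDF5, strict
  YAML configs, and a `ghostmd` command-line tool
  (`gen-data | train | md | pimd | inject | alchemy | analyze`).

See `docs/methods.md` for the models, conventions and frozen study
conditions, and for what the synthetic system does and does not show.

## A worked example

Run the explicit-ghost reference dynamics and look at the cavity:

```python
import numpy as np
from ghostmd import (ToyModelParams, build_box, relax_ghost,
                     AdiabaticGhostPotential, MDOptions, run_md)
from ghostmd.analysis import void_center, rdf_about_centers, coordination_number

params = ToyModelParams()                      # frozen toy-fluid + ghost coupling
box = build_box(32, density=1.3, seed=1, params=params)

pot = AdiabaticGhostPotential(box, params)     # ghost re-relaxed every step
traj = run_md(box, pot, MDOptions(dt=0.5, steps=10000, temperature=300.0,
                                  thermostat="langevin", friction=0.1,
                                  seed=1, stride=20))

ghost = relax_ghost(traj.frame_config(traj.n_frames - 1), params)
print(f"relaxed ghost energy: {ghost.energy:+.3f} eV (converged={ghost.converged})")

half = traj.n_frames // 2
centers = [None] * half
warm = ghost.position
for i in range(half, traj.n_frames):
    g = relax_ghost(traj.frame_config(i), params, init=warm)
    warm = g.position
    centers.append(g.position[None, :])
rdf_h = rdf_about_centers(traj, centers, "H", r_max=4.4, n_bins=22,
                          single_cavity_only=False)

near_h, near_o = [], []
for i in range(half, traj.n_frames):
    cfg = traj.frame_config(i)
    d = cfg.distances_to(centers[i][0])
    near_h.append(d[cfg.is_element("H")].min())
    near_o.append(d[cfg.is_element("O")].min())
print(f"nearest site to the center: H at {np.mean(near_h):.2f} Å, "
      f"O at {np.mean(near_o):.2f} Å (H lines the cavity)")
print(f"H sites within 3.0 Å of the center: "
      f"{coordination_number(rdf_h, r_cut=3.0):.1f}")
rec = void_center(traj.frame_config(traj.n_frames - 1), grid_spacing=0.45)
print(f"maximin void radius: {rec.maximin_radii[0]:.2f} Å "
      f"(twin cavity: {rec.twin})")
```

prints

```
relaxed ghost energy: +2.350 eV (converged=True)
nearest site to the center: H at 2.39 Å, O at 3.22 Å (H lines the cavity)
H sites within 3.0 Å of the center: 6.9
maximin void radius: 2.57 Å (twin cavity: False)
```

— the ghost sits in a cavity whose nearest neighbors are H sites (OH
moieties pointing inward), with a maximin void radius well above the neat
fluid's background (≤ 2.4 Å), which is what the void-based cavity detector
keys on.  Training the ghost-free potential on such data and verifying that
it keeps, and re-creates, this cavity without any ghost present is the
package's central experiment (`ghostmd.study.build_study_models`,
`ghost_free_fidelity_study`, `injection_study`).

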