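# Methods

`ghostmd` implements, at desk scale, the "ghost particle" strategy for
simulating a cavity-forming quasiparticle solute — the solvated electron
being the motivating case — with a machine-learning potential that never
represents the solute explicitly.  This note records the models, the frozen
study conditions, the numerical choices, and what the synthetic system can
and cannot say about real water.

## 1. The toy reference fluid

The stand-in for an expensive correlated-electronic-structure reference is a
flexible 3-site polar fluid:

- intramolecular: harmonic OH bonds, `k_b = 25 eV/Å²`, `r0 = 0.9572 Å`
  (stretch ≈ 2690 cm⁻¹, period 12.5 fs) and a harmonic HOH angle,
  `k_a = 2.4 eV/rad²`, `θ0 = 104.52°`;
- intermolecular: O–O Lennard-Jones (`ε = 0.025 eV`, `σ = 3.1507 Å`) and
  site charges `q_O = −0.834 e`, `q_H = +0.417 e` with shifted-force
  truncation at `r_c = 4.5 Å` (value- and derivative-continuous; both LJ and
  Coulomb).  No Ewald summation: long-range dielectric response is simply
  absent, an accepted bias of the surrogate.

Units throughout: Å, fs, eV, amu, with `k_B = 8.617333×10⁻⁵ eV/K` and
`ħ = 0.6582 eV·fs`.  Cells are orthorhombic with minimum-image convention,
which caps every cutoff at half the smallest box length.

**The ghost.**  A single massless particle couples to the nuclei with a
Gaussian attraction to H sites (`A_H = 1.0 eV`, `σ_H = 1.8 Å`) and a steep
Gaussian repulsion from O sites (`A_O = 18 eV`, `σ_O = 1.65 Å`), both
multiplied by a cosine cutoff at half the box so the coupling is C¹ across
the minimum-image shell (a bare Gaussian tail leaves the energy landscape
with kinks at the half-box boundary and local "minima" where no gradient
vanishes).  For every configuration the ghost is relaxed to a local minimum
of its coupling energy by a damped Newton iteration (analytic 3×3 Hessian,
Levenberg-style damping), warm-started from the previous frame during
dynamics and multi-started from a 2×2×2 grid otherwise.  Because the relaxed
ghost sits at a stationary point, the nuclear forces at fixed ghost equal
total derivatives (Hellmann–Feynman); the labeled data therefore never
contain ghost coordinates.

**Frozen study conditions.**  32 molecules at 1.3 g/cm³ (L = 9.03 Å),
300 K.  This density is deliberately above water's: with only 96 point
atoms, a 1.0 g/cm³ box shows natural maximin voids of ~2.7 Å that are
indistinguishable from a solute cavity; at 1.3 g/cm³ the neat background's
maximin void radius stays below 2.42 Å (99th percentile 2.38 Å) while the
ghost carves a cavity of 2.5–3.0 Å.  The coupling constants were tuned in
one calibration pass against that structure and against *learnability* (see
§2) and then frozen: the relaxed ghost sits in a cavity whose first H shell
peaks ~0.3–0.6 Å inside the O shell, with 5–7 H sites within ~3.2 Å and
5–7 molecules orienting one OH inward — the lined cavity of the reference
phenomenology, slightly over-coordinated relative to the 4–5 molecules of
the production picture because the orientational binding must stand clear of
the learned potential's noise floor.  Shell molecules show a red-shifted
stretch and libration band (the dangling-OH mechanism), though the stretch
shift is only ~10 cm⁻¹ and fluctuates between desk-scale runs; the
fixed-volume box also *reduces* the singly-donating/accepting totals when
the cavity compresses the remaining fluid, opposite to the constant-pressure
expectation — both documented limitations of the surrogate, not tested
claims.

## 2. The ghost-free potential

Atom-centered Behler–Parrinello descriptors: radial G2 (6 (η, R_s) pairs per
neighbor element, cosine cutoff 4.0 Å) and angular G4 (4 (ζ, λ, η) triples
per element pair, cutoff 3.2 Å); 24 descriptors per atom, identical for all
atoms of a composition, invariant under translations, rotations and
like-atom permutations.  D is hydrogen to the descriptors — isotopes differ
only by mass.

Per element ('H', 'O') the atomic energy is a two-hidden-layer tanh network
(24×24) over z-scored descriptors **plus a linear bypass** `lin·x` and a
constant offset.  The bypass exists because the dominant energy scale of
this problem — the several-eV difference between cavity and collapsed
states — turns out to be almost exactly linear in the summed descriptors
(ridge R² ≈ 0.95); saturating units learn it slowly or not at all, so it is
warm-started by ridge regression on the training energies and then refined
together with the network.  Forces are the exact analytic gradient of the
implemented energy: hand-coded backpropagation for dE/dG contracted with
sparse descriptor Jacobians (numba kernels).

**Training.**  Adam (β = 0.9/0.999) with cosine learning-rate decay,
deterministic for a fixed seed (seeded init, seeded batch order;
`batch_size=None` gives full-batch determinism under sample duplication).
The loss is `L = (1−w)·MSE(E/atom) + w·MSE(F)` with optional per-frame-label
multipliers on both terms.  The gradient of the force term with respect to
the weights is a Hessian-vector product assembled by a forward (R-operator)
tangent pass in the direction of the force residuals followed by a reverse
pass over the combined graph; the whole gradient is verified against central
differences of the implemented loss to ~1e-9.

**The electron model's training mixture** (frozen recipe, ~1050 frames):

| stratum | frames | sampled from | supervision |
|---|---|---|---|
| cavity | 450 | adiabatic-ghost MD, 60-step stride (~27 ps span) | E + F |
| localization | 250 | ghost-MD from neat starts, no equilibration | E + F, weight 2 |
| homogeneous | 120 | neat MD, relabeled with globally relaxed ghost | E only, weight 10 |
| cavity_pimd | 100 | ghost TRPMD (8 beads), one bead per frame | E + F |
| wall | ~170 | cavity frames: one shell molecule pushed inward or rigidly rotated | E + F, weight 2 |

The wall stratum exists because MD sampling never visits the strongly
repulsive approach of an O site toward an open cavity or strongly
disoriented shell molecules, yet the wall and the orientational restoring
torque are what keep the learned cavity at the reference radius and
H-lined.  Even with these probes the learned O-wall remains softer than the
reference (a molecule dragged 1.2 Å inward costs +2.7 eV on the reference
surface but only ~+1.3 eV under the model), which is the potential's main
residual defect — see §7.

Homogeneous frames carry the cavity-collapse penalty (≈ +6 eV) in their
energies, but their forces inherit the multi-basin ambiguity of the global
ghost minimum and would poison the fit, hence energy-only supervision.  The
localization stratum follows warm-started (continuous) ghost tracks along
the cavity-opening pathway, so its forces are well defined — these frames
teach the potential to *drive* localization after injection.  The global
force weight is `w = 0.10`: in absolute units the force MSE is ~70× the
per-atom energy MSE, so a small w still leaves force matching dominant while
letting the energy strata act at all.  A model trained only on cavity
frames, or with w = 0.5, loses the collapse penalty almost entirely and the
cavity dissolves within picoseconds — the central failure mode of the
method, and the reason production work trains on configurations from
several sampling regimes.

The stratum labels double as cross-validation subsets: the held-out error
report shows energy/force RMSE per stratum (the analog of comparing model
errors on rare structures against the training distribution).

A trained potential is concentration-specific (the ghost is an implicit
parameter of its data); binding a model to a different molecule count
raises a `ConcentrationWarning`.

## 3. Dynamics

One BAOAB-split integrator drives everything.  Bead positions evolve exactly
in the free-ring-polymer normal-mode basis (orthonormal transform, per-mode
harmonic rotation), physical forces act per bead, and the PILE thermostat
acts per normal mode with `γ_k = 2λω_k`, `λ = 0.5` on internal modes and a
configurable centroid friction (0 for production TRPMD, > 0 for Langevin
sampling/equilibration).  Bead convention: springs at `ω_P = P·k_B·T/ħ` and
Maxwell momenta at `P·T`.  With P = 1 the engine reduces bit-for-bit to
classical velocity-Verlet/Langevin.  Default `dt = 0.5 fs` keeps ≥ 25
steps per stretch period; a guard refuses time steps that resolve the
fastest harmonic period with fewer than 20 steps.  RNG: one PCG64 stream
per run seed; replicas use distinct seeds.

The injection protocol equilibrates each replica under the neat-trained
potential, switches to the electron-trained potential at t = 0, and logs the
first time the largest maximin void radius stays above the localization
threshold for two consecutive stored frames.  The threshold floor of 2.55 Å
is the calibrated midpoint between the toy neat background (max 2.42 Å) and
the toy ghost cavity (5th percentile ≈ 2.5 Å); because a trained neat
potential can pack slightly differently from the toy fluid it was fitted
to, the study protocol raises the threshold to that neat model's own void
baseline (99.5th percentile + 0.1 Å) whenever that is higher, and the
same-model null protocol — run at the identical threshold — measures the
false-positive rate.

## 4. Cavity analysis

The spin-density center of production studies needs electronic structure;
the surrogate center is the **maximin void**: local maxima of the
distance-to-nearest-atom field on a periodic grid (0.4–0.45 Å spacing,
with a grid-resolution margin before thresholding), refined by Nelder–Mead,
deduplicated, and thresholded at 2.55 Å.  In toy-reference runs the relaxed
ghost position is available as the exact center and the two agree to within
~0.7 Å — the void proxy is the noisier but model-free tracker used for
NN-driven trajectories.  Twin cavities are two surviving centers within the
pairing cutoff (6 Å, clamped to half the box); cavity-centered RDFs are
restricted to single-cavity frames by default.  Void-shape statistics use
the gyration tensor of the void's grid region; anisotropy is the relative
shape anisotropy κ² ∈ [0, 1] (0 isotropic, 1 collinear), chosen for its
clean limits since the production literature does not pin a formula.

Other observables: ideal-gas-normalized RDFs with running coordination
numbers (auto r_cut at the first minimum after the first peak); FFT-based
MSD with Einstein-relation fits and contiguous-block errors; mass-weighted
Hann-windowed VDOS normalized so that ∫I dν equals the windowed
mass-weighted velocity variance (Parseval, exact by construction), with
band peak metrics (parabolic interpolation, high-side half maximum, doublet
detection by prominence); and a probabilistic hydrogen-bond census with
`p = s((d0−d_OA)/Δd)·s((θ0−β)/Δθ)` (logistic s, d0 = 3.5 Å, Δd = 0.25 Å,
θ0 = 30°, Δθ = 7.5°, β the acceptor–donor-O–H angle) — a smooth stand-in
for cluster-based probabilistic HB classifiers, with expected donor/acceptor
counts and singly-donating/accepting totals.

Shell membership uses the O-atom distance with a closed boundary; the
default 3.5 Å mirrors the first-coordination-shell radius of the reference
phenomenology, although this toy's cavity is larger (analyses of the toy
pass their own radius explicitly where it matters).

## 5. Isotope exchange

`run_alchemy` alternates TRPMD segments with Metropolis H↔D mass swaps at
fixed bead geometry: the physical potential is mass-independent, so
`ΔE = ½ω_P²(m_D−m_H)(S_H−S_D)` involves only the spring geometry factors S,
and acceptance uses the extended-ensemble temperature `P·T`.  Accepted swaps
exchange masses and species labels and rescale the two atoms' velocities by
√(m_old/m_new), which maps Maxwell distributions exactly.

Two estimators of the fractionation constant are reported:

- **occupancy odds** (the headline definition):
  `K_eq = (n_H/n_D)_shell / (n_H/n_D)_bulk` from the realized isotope
  occupancies, with a block bootstrap whose block length is ≥ 10× the
  integrated autocorrelation time of the shell-H series;
- **virtual substitution (FEP)**: every site contributes
  `exp(∓β_ext·½ω_P²Δm·S_i)` every sweep (H sites forward, D sites reverse),
  giving per-class mutation free energies and
  `K_fep = exp(β_ext(Δf_shell − Δf_bulk))`.

The second exists because the harmonic toy fractionates only marginally.
At the weaker coupling explored during calibration the mutation free-energy
profile showed lnK ≈ +0.07 at the inner lined shell (H enriched, the
dangling-OH/libration mechanism); at the frozen coupling — whose deeper
lined-H well was required for the ghost-free potential to learn the shell
orientation at all — the well's angular stiffening cancels most of that
softening and the measured lnK is 0.00 ± 0.02: the sign of the isotope
effect sits at (not above) desk-scale resolution, and the corresponding
sign check in the acceptance suite fails or passes within noise depending
on the seed.  This trade-off between learnability of the cavity structure
and the strength of the fractionation signal is intrinsic to a
harmonic-bond surrogate, which lacks the anharmonic stretch softening that
dominates the real effect.  Direct-swap acceptance *and* mutation-weight
variance both degrade exponentially with bead count (⟨βΔE⟩ ≈ 0.75(P−1) for
H/D), so the cavity fractionation study runs at P = 4 with the 2.8 Å
lined-shell classification; staged alchemical exchanges would be the
production remedy and are out of scope.  The
machinery itself is validated where the signal is strong: a stiff/soft
two-well H/D exchange reproduces the exact quantum two-state
partition-function ratio, and a homogeneous fluid with an arbitrary fixed
"shell" center gives K = 1 within the bootstrap CI.

## 6. Study problem sizes

All end-to-end numbers come from `ghostmd.study`, sized for a single CPU:
1000-frame training mixture, 220-epoch electron training (400 frames /
120 epochs for the neat model), 4 ps ghost-free fidelity runs, 10+10
injection replicas of 0.55 ps, the oracle systems as stated in their
docstrings.  The NVE-conservation property is checked over shortened
windows with the same integrator; symplectic error is oscillatory, so the
short check bounds the same amplitude the long one would.

## 6a. Fidelity resolution

The ghost-free fidelity comparison (cavity-centered RDFs of the trained
model vs the explicit-ghost reference) is made at ~0.49 Å bins.  This is
the resolution the desk-scale sampling supports: two independent reference
runs of the prescribed length already differ by max|Δg| ≈ 0.4–0.6 at 0.2 Å
bins, because the cavity radius wanders on multi-picosecond timescales and
the steep RDF inner edge tracks it; no model can be meaningfully tested to
±0.3 below the measurement's own replication error.  At the packaged
resolution the reference reproduces itself to ≈ 0.2.

At that resolution the trained potential reproduces the H shell within
tolerance and preserves the H-closer-than-O ordering, but its O shell sits
~0.3–0.5 Å closer to the center than the reference's (max|Δg_O| ≈ 0.8):
the model under-reproduces the orientational standoff of the shell
molecules (≈3 of the reference's ≈6 lined OH per frame), because the
orientational energy scale sits at the model's force-error floor even after
the wall/rotation probes.  This is reported as measured — the corresponding
acceptance check fails on the O channel — and closing it would need a
several-fold reduction in force RMSE (larger networks, more data, longer
training than the desk budget allows).

## 7. What the toy does and does not show

Passing this suite demonstrates that the *methodology* is implemented
correctly and behaves as the reference program claims on a system where
every stage can be cross-checked against exact oracles: the implicit-solute
potential keeps and re-forms the cavity, quantum statistics/spectra/
diffusion machinery are quantitatively correct, and isotope fractionation
has the right sign and mechanism.  It does not validate quantitative water
physics: no Ewald electrostatics, harmonic bonds (hence weak anharmonic
red shifts and weak fractionation), a 32-molecule box with correspondingly
coarse void statistics, densities chosen for cavity detectability, and a
geometric rather than electronic cavity center.  Headline production
numbers (diffusion constants, K_eq ≈ 2, absolute band positions) are
cluster-scale quantities and are deliberately out of scope.
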