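# Frozen defaults for the whole pipeline.  Every run resolves its
# configuration against this file and writes the result next to its outputs.
toy:
  n_molecules: 32
  density: 1.3          # g/cm^3
  temperature: 300.0    # K
  k_bond: 25.0          # eV/A^2
  r0: 0.9572            # A
  k_angle: 2.4          # eV/rad^2
  theta0: 1.82421813    # rad
  lj_epsilon: 0.025     # eV
  lj_sigma: 3.1507      # A
  q_O: -0.834           # e
  q_H: 0.417            # e
  r_cut: 4.5            # A
  ghost_A_H: 1.0        # eV
  ghost_sigma_H: 1.8    # A
  ghost_A_O: 18.0       # eV
  ghost_sigma_O: 1.65   # A

model:
  hidden: [24, 24]
  epochs: 120
  lr: 0.01
  force_weight: 0.5
  batch_size: 32
  val_fraction: 0.1
  r_cut: 4.0            # descriptor radial cutoff, A
  r_cut_angular: 3.2

dynamics:
  dt: 0.5               # fs
  steps: 2000
  thermostat: langevin
  friction: 0.05        # 1/fs
  pile_lambda: 0.5
  n_beads: 16
  stride: 10

alchemy:
  md_steps: 60
  n_sweeps: 200
  equil_sweeps: 20
  shell_radius: 3.5     # A

analysis:
  grid_spacing: 0.4     # A
  radius_threshold: 2.55 # A, maximin void radius for a cavity
  pairing_cutoff: 6.0   # A, twin-cavity pairing
  r_shell: 3.5          # A
  rdf_bins: 60

seed: 0
output_dir: runs
log_level: INFO
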