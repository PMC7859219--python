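"""Internal unit system and physical constants.

Everything inside the package works in Å (length), fs (time), eV (energy)
and amu (mass).  Because eV and amu·Å²/fs² are different energy units, a
single conversion factor ``MASS_EV`` appears wherever kinetic energy,
thermal velocities or accelerations are formed:

    E_kin [eV] = 0.5 * m [amu] * v² [Å²/fs²] * MASS_EV
    a [Å/fs²]  = F [eV/Å] / (m [amu] * MASS_EV)
"""

#: Boltzmann constant, eV/K.
KB = 8.617333e-5

#: Reduced Planck constant, eV·fs.
HBAR = 0.6582119569

#: 1 amu·Å²/fs² expressed in eV.
MASS_EV = 103.64269572045

#: Coulomb constant e²/(4π ε0), eV·Å.
COULOMB = 14.399645

#: Speed of light, cm/fs (converts frequency in 1/fs to wavenumber in cm⁻¹).
C_CM_FS = 2.99792458e-5

#: Atomic masses, amu.  D is hydrogen-like in every potential; only the mass differs.
ATOMIC_MASSES = {"O": 15.999, "H": 1.008, "D": 2.014}

#: Chemical element behind each species label (descriptors and networks see this).
ELEMENT_OF = {"O": "O", "H": "H", "D": "H"}
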