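"""Physical constants in the unit system used throughout the package.

Energies are kcal/mol, distances Å, times ns (internal) / ps (trajectory
stride, at the I/O boundary), temperatures K, angles degrees.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_MOL_K = 1.9872e-3

PS_PER_NS = 1000.0
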