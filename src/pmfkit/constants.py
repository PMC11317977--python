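"""Physical constants used package-wide.

All energies are in kcal/mol, lengths in angstrom, charges in elementary
charges, temperatures in kelvin.  No unit autodetection happens anywhere.
"""

#: Boltzmann constant, kcal mol^-1 K^-1
KB = 0.0019872041

#: Coulomb constant, kcal A mol^-1 e^-2
COULOMB = 332.0637

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 300.0
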