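"""Unit constants and conversions.

Internal conventions: energies in Hartree, distances in Angstrom for
geometries, the mass-weighted reaction coordinate xi in amu^(1/2)*bohr,
forces in Hartree/bohr. Conversions to kcal-based units happen only at
reporting time.
"""

HARTREE_TO_KCAL_PER_MOL = 627.5094740631
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

#: Gaussian-style route files express the IRC step size as an integer in
#: units of 0.01 amu^(1/2)*bohr (0.8 amu^(1/2)*bohr -> "stepsize=80").
IRC_STEPSIZE_DIALECT_FACTOR = 100.0
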