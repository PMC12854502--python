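"""Physical constants and unit conversions used across the package."""

#: 1 hartree in electronvolts (CODATA).
HARTREE_TO_EV = 27.211386

#: 1 angstrom in bohr radii (CODATA).
ANGSTROM_TO_BOHR = 1.0 / 0.529177210903

#: Occupation (electrons) separating occupied from virtual MOs.  Only
#: closed-shell integer occupations are in scope, so any value strictly
#: between 0 and 2 works; 0.5 is robust to numerical noise.
OCCUPATION_THRESHOLD = 0.5

#: Minimum interatomic separation (bohr) accepted by the point-charge
#: condensed potentials; below this the 1/r kernel is considered divergent.
MIN_SEPARATION_BOHR = 0.1
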