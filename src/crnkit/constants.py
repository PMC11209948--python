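"""Physical constants and default element tables.

All constants are CODATA 2018 values, pinned here so every rate expression
in the package draws from a single source.
"""

from __future__ import annotations

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314462618

#: Boltzmann constant, J K^-1.
K_BOLTZMANN = 1.380649e-23

#: Avogadro constant, mol^-1.
N_AVOGADRO = 6.02214076e23

#: Single-bond covalent radii in Angstrom.  Classic crystallographic set;
#: H is 0.37 A so that H2 (r = 0.74 A) is perceived as bonded at the
#: default cutoff scaling alpha = 1.1.  Overridable via CovalentRadiiTable.
COVALENT_RADII = {
    "H": 0.37,
    "He": 0.32,
    "B": 0.82,
    "C": 0.77,
    "N": 0.75,
    "O": 0.73,
    "F": 0.71,
    "Si": 1.11,
    "P": 1.06,
    "S": 1.02,
    "Cl": 0.99,
    "Br": 1.14,
    "I": 1.33,
}

#: Default maximum valences (graph degree limits) per element.
MAX_VALENCE = {
    "H": 1,
    "C": 4,
    "N": 3,
    "O": 2,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
    "S": 2,
    "P": 3,
    "Si": 4,
}

#: Atomic molar masses, g mol^-1 (for collision-theory reduced masses).
MOLAR_MASS = {
    "H": 1.008,
    "He": 4.0026,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "S": 32.06,
    "Cl": 35.45,
}
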