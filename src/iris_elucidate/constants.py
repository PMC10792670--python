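"""Physical constants and the bundled monoisotopic isotope table.

Masses are IUPAC monoisotopic (most abundant isotope) atomic masses in Da.
The table can be extended or overridden per call through the ``isotope_table``
arguments of the mass functions; these module-level values are the defaults.
"""

from __future__ import annotations

# most-abundant-isotope masses, Da
ISOTOPE_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "P": 30.97376163,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
    "K": 38.96370668,
    "Si": 27.97692653,
}

ELECTRON_MASS: float = 0.00054857990924  # Da

PROTON_MASS: float = ISOTOPE_MASSES["H"] - ELECTRON_MASS

#: molar gas constant, J mol^-1 K^-1
R_GAS: float = 8.314462618

#: Hartree -> kJ/mol conversion
HARTREE_TO_KJ_MOL: float = 2625.4996394799
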