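"""Packaged atomic mass tables.

Monoisotopic masses are the most-abundant-isotope masses (CODATA/AME);
average masses are IUPAC standard atomic weights (conventional values for
elements with an abundance interval). The set covers the elements that occur
in sulfonamide inhibitor chemistry plus common salt adducts; unknown symbols
are rejected at parse time rather than silently defaulting.
"""

from __future__ import annotations

# symbol -> (monoisotopic mass, standard atomic weight), Da
ELEMENTS: dict[str, tuple[float, float]] = {
    "H": (1.00782503207, 1.008),
    "C": (12.0, 12.011),
    "N": (14.0030740048, 14.007),
    "O": (15.9949146196, 15.999),
    "F": (18.99840322, 18.998403163),
    "S": (31.97207100, 32.06),
    "P": (30.97376163, 30.973761998),
    "Cl": (34.96885268, 35.45),
    "Br": (78.9183371, 79.904),
    "I": (126.904473, 126.90447),
    "Na": (22.98976928, 22.98976928),
    "K": (38.96370668, 39.0983),
    "B": (11.0093054, 10.81),
    "Si": (27.97692653, 28.085),
    "Se": (79.9165213, 78.971),
    "Zn": (63.9291422, 65.38),
}

ELECTRON_MASS = 0.000548579909  # Da

#: proton mass (H minus electron); the +-1 charge carriers used for m/z
PROTON_MASS = ELEMENTS["H"][0] - ELECTRON_MASS  # 1.00727646...
SODIUM_CATION_MASS = ELEMENTS["Na"][0] - ELECTRON_MASS  # 22.98922...
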