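"""Pinned isotope masses/abundances and standard atomic weights.

Values are IUPAC/CIAAW (isotopic masses from the AME2020-based CIAAW
compilation, abundances from the 2021 representative values). The table is
frozen inside the package so that isotope-pattern simulations and the
isotopic-fit score are bit-stable across environments. Symbols "D" and
"[13C]" denote pure 2H and pure 13C, used for isotope-labeled internal
standards (e.g. ciprofloxacin-d8, azithromycin-13Cd3).
"""

from __future__ import annotations

# symbol -> tuple of (exact mass [Da], abundance), sorted by mass ascending.
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.0078250319, 0.999885), (2.0141017779, 0.000115)),
    "D": ((2.0141017779, 1.0),),
    "C": ((12.0, 0.9893), (13.0033548351, 0.0107)),
    "[13C]": ((13.0033548351, 1.0),),
    "N": ((14.0030740052, 0.99636), (15.0001088984, 0.00364)),
    "O": (
        (15.9949146221, 0.99757),
        (16.9991315012, 0.00038),
        (17.9991604, 0.00205),
    ),
    "F": ((18.9984031627, 1.0),),
    "Na": ((22.9897692809, 1.0),),
    "P": ((30.9737615120, 1.0),),
    "S": (
        (31.9720707300, 0.9499),
        (32.9714585430, 0.0075),
        (33.9678669000, 0.0425),
        (35.9670812000, 0.0001),
    ),
    "Cl": ((34.9688527100, 0.7576), (36.9659026000, 0.2424)),
    "K": (
        (38.9637064900, 0.932581),
        (39.9639982000, 0.000117),
        (40.9618252600, 0.067302),
    ),
    "Br": ((78.9183376000, 0.5069), (80.9162897000, 0.4931)),
    "I": ((126.9044719000, 1.0),),
}

# Standard atomic weights (IUPAC 2021 abridged; conventional value where an
# interval is published). Pure labels use their isotopic mass.
AVERAGE_MASS: dict[str, float] = {
    "H": 1.008,
    "D": 2.0141017779,
    "C": 12.011,
    "[13C]": 13.0033548351,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Na": 22.98976928,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.0983,
    "Br": 79.904,
    "I": 126.90447,
}

#: Mass of a proton (Da); the electron mass is already accounted for.
PROTON_MASS = 1.00727646677
#: Mass of an electron (Da).
ELECTRON_MASS = 0.00054857990907

SUPPORTED_ELEMENTS = frozenset(ISOTOPES)
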