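"""Physical constants for exact-mass calculus.

Monoisotopic masses are CODATA/IUPAC values for the most abundant isotope
of each supported element, quoted to at least six decimal places so that
calculated neutral masses reproduce published 4-dp values and ppm errors
reproduce published 2-dp values.  Isotope abundance tables are IUPAC
representative terrestrial compositions, used for nominal-mass (A, A+1,
A+2, ...) envelope simulation.
"""

from __future__ import annotations

#: Mass of a proton in Da (electron-corrected H+; used for adduct offsets).
PROTON_MASS = 1.00727646688

#: Electron rest mass in Da.
ELECTRON_MASS = 0.00054857990907

#: Monoisotopic (most-abundant-isotope) atomic masses in Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

#: Per-element isotope distributions as ``{element: [(nominal offset from the
#: monoisotopic isotope, exact mass, abundance), ...]}``.  Abundances sum to 1
#: per element.  Monoisotopic entry first; offsets in integer nominal units.
ISOTOPES: dict[str, list[tuple[int, float, float]]] = {
    "C": [(0, 12.0, 0.9893), (1, 13.00335483507, 0.0107)],
    "H": [(0, 1.00782503207, 0.999885), (1, 2.01410177785, 0.000115)],
    "N": [(0, 14.0030740048, 0.99636), (1, 15.0001088982, 0.00364)],
    "O": [
        (0, 15.99491461956, 0.99757),
        (1, 16.99913170, 0.00038),
        (2, 17.99916100, 0.00205),
    ],
    "P": [(0, 30.97376163, 1.0)],
    "S": [
        (0, 31.97207100, 0.9499),
        (1, 32.97145876, 0.0075),
        (2, 33.96786690, 0.0425),
        (4, 35.96708076, 0.0001),
    ],
    "Cl": [(0, 34.96885268, 0.7577), (2, 36.96590259, 0.2423)],
    "Br": [(0, 78.9183371, 0.5069), (2, 80.9162906, 0.4931)],
    "Na": [(0, 22.9897692809, 1.0)],
    "K": [
        (0, 38.96370668, 0.932581),
        (1, 39.96399848, 0.000117),
        (2, 40.96182576, 0.067302),
    ],
}

#: Elements accepted by the formula parser.
SUPPORTED_ELEMENTS = frozenset(MONOISOTOPIC_MASS)
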