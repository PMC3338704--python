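"""Constant tables shared across the package.

Everything residue-indexed in this package uses one canonical alphabet
order: A, R, N, D, C, Q, E, G, H, I, L, K, M, F, P, S, T, W, Y, V.
"""

from __future__ import annotations

import numpy as np

#: Canonical 20-letter amino-acid alphabet order.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Three-letter residue names, canonical order (used for feature slot names).
AA_THREE = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

# Robinson & Robinson amino-acid background frequencies, the background
# distribution distributed with the BLOSUM62 substitution data (as used by
# BLAST).  Canonical order; sums to 1.00000 in decimal.
BLOSUM62_BACKGROUND = np.array([
    0.07805,  # A
    0.05129,  # R
    0.04487,  # N
    0.05364,  # D
    0.01925,  # C
    0.04264,  # Q
    0.06295,  # E
    0.07377,  # G
    0.02199,  # H
    0.05142,  # I
    0.09019,  # L
    0.05744,  # K
    0.02243,  # M
    0.03856,  # F
    0.05203,  # P
    0.07120,  # S
    0.05841,  # T
    0.01330,  # W
    0.03216,  # Y
    0.06441,  # V
])

#: Taylor's ten overlapping amino-acid property classes, in the fixed order
#: used for the 10-bit property encoding and the class-based conservation
#: score.  Classes overlap: one residue may belong to several.
TAYLOR_CLASSES = (
    ("Polar", frozenset("NQSDECTKRHYW")),
    ("Positive", frozenset("KHR")),
    ("Negative", frozenset("DE")),
    ("Charged", frozenset("KHRDE")),
    ("Hydrophobic", frozenset("AGCTIVLKHFYWM")),
    ("Aliphatic", frozenset("IVL")),
    ("Aromatic", frozenset("FYWH")),
    ("Small", frozenset("PNDTCAGSV")),
    ("Tiny", frozenset("ASGC")),
    ("Proline", frozenset("P")),
)

CLASS_NAMES = tuple(name for name, _ in TAYLOR_CLASSES)

# Sweet & Eisenberg optimal-matching hydrophobicity (OMH) scale, canonical
# order.  Non-canonical letters get 0 wherever this scale is consulted.
SWEET_EISENBERG = {
    "A": -0.40, "R": -0.59, "N": -0.92, "D": -1.31, "C": 0.17,
    "Q": -0.91, "E": -1.22, "G": -0.67, "H": -0.64, "I": 1.25,
    "L": 1.22, "K": -0.67, "M": 1.02, "F": 1.92, "P": -0.49,
    "S": -0.55, "T": -0.28, "W": 0.50, "Y": 1.67, "V": 0.91,
}

#: Members of the Polar and Charged classes combined — the residue pool the
#: synthetic generator samples planted catalytic sites from.
POLAR_OR_CHARGED = sorted(
    frozenset("NQSDECTKRHYW") | frozenset("KHRDE"), key=AA_INDEX.get
)
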