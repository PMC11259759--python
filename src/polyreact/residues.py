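"""Amino-acid scales shared across the package.

Charge is the formal side-chain charge at pH 7.4 (K/R +1, D/E -1, His +0.1
for its partial protonation); hydrophobicity is the Kyte-Doolittle scale.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Side-chain charge at pH 7.4.
CHARGE_PH74: dict[str, float] = {aa: 0.0 for aa in AMINO_ACIDS}
CHARGE_PH74.update({"K": 1.0, "R": 1.0, "H": 0.1, "D": -1.0, "E": -1.0})

AROMATIC: frozenset = frozenset("FWYH")
POSITIVE: frozenset = frozenset("KR")


def is_valid_sequence(seq: str) -> bool:
    """True when every character is one of the 20 standard residue letters."""
    return bool(seq) and all(c in AA_INDEX for c in seq)


def net_charge(seq: str) -> float:
    """Additive net side-chain charge of *seq* at pH 7.4."""
    return sum(CHARGE_PH74[c] for c in seq)


def mean_hydrophobicity(seq: str) -> float:
    """Mean Kyte-Doolittle hydropathy; 0.0 for an empty sequence."""
    if not seq:
        return 0.0
    return sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)


def aromatic_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(c in AROMATIC for c in seq) / len(seq)


def positive_count(seq: str) -> int:
    return sum(c in POSITIVE for c in seq)
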