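"""Shared constants: alphabets, hydrophobicity scales, residue classes.

All scales are indexed by one-letter amino-acid code (uppercase). The
20-letter alphabet is kept in alphabetical order throughout the package so
that position-weight matrices, logos and consensus tie-breaking are
reproducible.
"""

from __future__ import annotations

import numpy as np

#: canonical amino-acid alphabet, alphabetical order
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
#: index used for the unknown/masked letter 'X'
X_INDEX = len(AA_ALPHABET)

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Eisenberg consensus hydrophobicity scale (used for hydrophobic moments)
EISENBERG_CONSENSUS = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
    "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
    "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
    "Y": 0.26, "V": 1.08,
}

HYDROPHOBICITY_SCALES = {
    "kyte-doolittle": KYTE_DOOLITTLE,
    "eisenberg-consensus": EISENBERG_CONSENSUS,
}

#: physico-chemical residue classes used for helical-wheel colouring
RESIDUE_CLASSES = {
    "hydrophobic": set("ACFILMVWY"),
    "basic": set("KRH"),
    "acidic": set("DE"),
    "uncharged-polar": set("STNQG"),
    "special": set("P"),
}

#: Coulomb constant f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458

#: lipid species of the model bilayer
LIPID_SPECIES = ("GLY", "PG", "DAG")


def scale_vector(scale: dict[str, float]) -> np.ndarray:
    """Return a scale as a length-20 vector in alphabet order."""
    return np.array([scale[a] for a in AA_ALPHABET], dtype=float)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a protein sequence as integer indices (X and unknowns -> 20)."""
    return np.array([AA_INDEX.get(c, X_INDEX) for c in seq.upper()],
                    dtype=np.int64)
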