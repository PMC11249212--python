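"""Kidera-factor physico-chemical descriptors for peptides.

The ten Kidera factors are orthogonal summaries of 188 physical
properties of the 20 standard amino acids (helix/bend preference,
side-chain size, extended-structure preference, hydrophobicity,
double-bend preference, partial specific volume, flat-extended
preference, alpha-helix occurrence, pK-C / partial charge, and a
surrounding-hydrophobicity term). Each factor is standardized to
approximately zero mean and unit variance over the 20 residues, so
averaging them across a peptide yields a comparable 10-dimensional
descriptor regardless of length. Here they summarize CDR3 amino-acid
sequences.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

#: Per-residue Kidera factor values, order KF1..KF10.
KIDERA_TABLE: dict[str, tuple[float, ...]] = {
    "A": (-1.56, -1.67, -0.97, -0.27, -0.93, -0.78, -0.20, -0.08, 0.21, -0.48),
    "R": (0.22, 1.27, 1.37, 1.87, -1.70, 0.46, 0.92, -0.39, 0.23, 0.93),
    "N": (1.14, -0.07, -0.12, 0.81, 0.18, 0.37, -0.09, 1.23, 1.10, -1.73),
    "D": (0.58, -0.22, -1.58, 0.81, -0.92, 0.15, -1.52, 0.47, 0.76, 0.70),
    "C": (0.12, -0.89, 0.45, -1.05, -0.71, 2.41, 1.52, -0.69, 1.13, 1.10),
    "Q": (-0.47, 0.24, 0.07, 1.10, 1.10, 0.59, 0.84, -0.71, -0.03, -2.33),
    "E": (-1.45, 0.19, -1.61, 1.17, -1.31, 0.40, 0.04, 0.38, -0.35, -0.12),
    "G": (1.46, -1.96, -0.23, -0.16, 0.10, -0.11, 1.32, 2.36, -1.66, 0.46),
    "H": (-0.41, 0.52, -0.28, 0.28, 1.61, 1.01, -1.85, 0.47, 1.13, 1.63),
    "I": (-0.73, -0.16, 1.79, -0.77, -0.54, 0.03, -0.83, 0.51, 0.66, -1.78),
    "L": (-1.04, 0.00, -0.24, -1.10, -0.55, -2.05, 0.96, -0.76, 0.45, 0.93),
    "K": (-0.34, 0.82, -0.23, 1.70, 1.54, -1.62, 1.15, -0.08, -0.48, 0.60),
    "M": (-1.40, 0.18, -0.42, -0.73, 2.00, 1.52, 0.26, 0.11, -1.27, 0.27),
    "F": (-0.21, 0.98, -0.36, -1.43, 0.22, -0.81, 0.67, 1.10, 1.71, -0.44),
    "P": (2.06, -0.33, -1.15, -0.75, 0.88, -0.45, 0.30, -2.30, 0.74, -0.28),
    "S": (0.81, -1.08, 0.16, 0.42, -0.21, -0.43, -1.89, -1.15, -0.97, -0.23),
    "T": (0.26, -0.70, 1.21, 0.63, -0.10, 0.21, 0.24, -1.15, -0.56, 0.19),
    "W": (0.30, 2.10, -0.72, -1.57, -1.16, 0.57, -0.48, -0.40, -2.30, -0.60),
    "Y": (1.38, 1.48, 0.80, -0.56, 0.00, -0.68, -0.31, 1.03, -0.05, 0.53),
    "V": (-0.74, -0.71, 2.04, -0.40, 0.50, -0.81, -1.07, 0.06, -0.46, 0.65),
}

#: The 20-letter amino-acid alphabet, in fixed order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

_KIDERA_MATRIX = np.array([KIDERA_TABLE[a] for a in AMINO_ACIDS])
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def kidera_descriptor(cdr3_aa: str) -> np.ndarray:
    """Mean Kidera-factor vector of a peptide.

    Parameters
    ----------
    cdr3_aa:
        Non-empty amino-acid sequence over the 20 standard residues.

    Returns
    -------
    numpy.ndarray
        Length-10 array, ``KF1..KF10``, the arithmetic mean of the
        per-residue factor values.

    Raises
    ------
    ValidationError
        If the sequence is empty or contains a non-standard residue
        (the error names the residue and its 1-based position).
    """
    if not cdr3_aa:
        raise ValidationError("CDR3 amino-acid sequence must be non-empty")
    try:
        idx = [_AA_INDEX[a] for a in cdr3_aa]
    except KeyError:
        for pos, a in enumerate(cdr3_aa, start=1):
            if a not in _AA_INDEX:
                raise ValidationError(
                    f"non-standard residue {a!r} at position {pos}"
                ) from None
        raise  # pragma: no cover
    return _KIDERA_MATRIX[idx].mean(axis=0)
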