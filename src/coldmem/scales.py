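"""Per-residue physicochemical scales used by the transmembrane predictors.

Two scales are shipped as data constants:

* the Kyte-Doolittle hydropathy index, used by the sliding-window
  hydropathy predictor (positive = hydrophobic);
* apparent free energies of membrane insertion (kcal/mol) from the
  translocon-based "biological" scale, used by the insertion-energy
  predictor (negative = favours insertion).
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Position-independent apparent dG of membrane insertion, kcal/mol.
DG_INSERTION: dict[str, float] = {
    "A": 0.11, "C": -0.13, "D": 3.49, "E": 2.68, "F": -0.32,
    "G": 0.74, "H": 2.06, "I": -0.60, "K": 2.71, "L": -0.55,
    "M": -0.10, "N": 2.05, "P": 2.23, "Q": 2.36, "R": 2.58,
    "S": 0.84, "T": 0.52, "V": -0.31, "W": 0.30, "Y": 0.68,
}


class UnknownResidueError(ValueError):
    """A sequence contained a character outside the 20-letter alphabet."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position  # 1-based
        super().__init__(f"unknown residue {residue!r} at position {position}")


def validate_sequence(seq: str) -> None:
    """Raise :class:`UnknownResidueError` naming the first bad position."""
    for i, aa in enumerate(seq):
        if aa not in _AA_INDEX:
            raise UnknownResidueError(aa, i + 1)


def residue_indices(seq: str) -> np.ndarray:
    """Map a validated sequence to integer indices into ``AMINO_ACIDS``."""
    validate_sequence(seq)
    return np.fromiter((_AA_INDEX[aa] for aa in seq), dtype=np.intp, count=len(seq))


def scale_values(seq: str, scale: dict[str, float]) -> np.ndarray:
    validate_sequence(seq)
    return np.fromiter((scale[aa] for aa in seq), dtype=float, count=len(seq))
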