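"""Residue property scales shared across modules."""

from __future__ import annotations

import numpy as np

#: The 20 canonical amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte-Doolittle hydropathy index. 'X' (unknown) scores 0 so that it is
#: effectively excluded from hydropathy windows.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


def hydropathy_profile(seq: str) -> np.ndarray:
    """Per-residue Kyte-Doolittle values."""
    return np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq], dtype=float)


def window_mean(seq: str, start: int, end: int) -> float:
    """Mean hydropathy over ``seq[start:end]`` (clipped to the sequence)."""
    start = max(0, start)
    end = min(len(seq), end)
    if end <= start:
        return 0.0
    return float(hydropathy_profile(seq[start:end]).mean())
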