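"""Kyte-Doolittle hydropathy: GRAVY score and sliding-window profiles."""

from __future__ import annotations

import numpy as np

from .records import validate_sequence
from .tables import KYTE_DOOLITTLE


def hydropathy_values(seq: str) -> np.ndarray:
    """Per-residue Kyte-Doolittle values as a float array."""
    seq = validate_sequence(seq)
    return np.array([KYTE_DOOLITTLE[aa] for aa in seq], dtype=float)


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value of the sequence."""
    return float(hydropathy_values(seq).mean())


def hydropathy_profile(seq: str, window: int = 19) -> np.ndarray:
    """Centered sliding-window mean hydropathy.

    Returns an array of length ``len(seq) - window + 1``; entry ``i`` is the
    mean over residues ``i+1 .. i+window`` (1-based), i.e. the window centred
    on residue ``i + (window+1)//2``.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    values = hydropathy_values(seq)
    if len(values) < window:
        raise ValueError(
            f"sequence length {len(values)} shorter than window {window}"
        )
    kernel = np.full(window, 1.0 / window)
    return np.convolve(values, kernel, mode="valid")
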