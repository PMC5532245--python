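"""Small numeric helpers shared across account builders."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (ledger convention).

    Python's built-in round() rounds halves to even; printed account tables
    use commercial rounding, so 0.5 -> 1 and -0.5 -> -1.
    """
    if math.isnan(x):
        raise ValueError("cannot round NaN")
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def round_half_away_arr(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5))
    return out
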