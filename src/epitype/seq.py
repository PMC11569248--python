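"""DNA sequence encoding helpers."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def one_hot(seq: str) -> np.ndarray:
    """(L, 4) encoding with A=[1,0,0,0], C, G, T; N/other rows are zero."""
    out = np.zeros((len(seq), 4))
    for i, b in enumerate(seq.upper()):
        j = _IDX.get(b)
        if j is not None:
            out[i, j] = 1.0
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def rc_one_hot(x: np.ndarray) -> np.ndarray:
    """Reverse-complement an (L, 4) one-hot array (reverse both axes)."""
    return x[::-1, ::-1].copy()
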