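"""Amino-acid alphabet and background composition shared across modules."""

from __future__ import annotations

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

# Robinson & Robinson average protein composition, renormalised over the
# 20-letter alphabet.  Used as the default background for profiles,
# conservation scores and the synthetic substitution process.
BACKGROUND = np.array(
    [
        0.07805,  # A
        0.01925,  # C
        0.05364,  # D
        0.06295,  # E
        0.03856,  # F
        0.07377,  # G
        0.02199,  # H
        0.05142,  # I
        0.05744,  # K
        0.09019,  # L
        0.02243,  # M
        0.04487,  # N
        0.05203,  # P
        0.04264,  # Q
        0.05129,  # R
        0.07120,  # S
        0.05841,  # T
        0.06441,  # V
        0.01330,  # W
        0.03216,  # Y
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()


def seq_to_indices(seq: str) -> np.ndarray:
    return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
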