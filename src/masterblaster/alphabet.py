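"""The 20-letter amino-acid alphabet, encodings and background frequencies.

Everything downstream (profiles, alignment kernels, the synthetic evolver)
uses the fixed column order ``ARNDCQEGHILKMFPSTWYV``, the order BLOSUM
matrices are conventionally printed in.  The unknown residue ``X`` is
tolerated in input sequences and carried as index 20.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue order for all 20-wide arrays.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Alphabet accepted in input sequences.
ALPHABET = AMINO_ACIDS + "X"

GAP = "-"

#: Index of the unknown residue in encoded sequences.
X_INDEX = 20

AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# Robinson & Robinson (1991) amino-acid background frequencies, the set used
# by BLAST's Karlin-Altschul statistics; normalized to sum exactly to 1.
_ROBINSON = np.array(
    [
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
    ]
)
BACKGROUND = _ROBINSON / _ROBINSON.sum()


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as an int8 array (X -> 20).

    Raises ``ValueError`` naming the first offending position for characters
    outside the alphabet.
    """
    out = np.empty(len(residues), dtype=np.int8)
    for i, ch in enumerate(residues):
        try:
            out[i] = AA_TO_INDEX[ch]
        except KeyError:
            raise ValueError(
                f"invalid residue {ch!r} at position {i + 1}"
            ) from None
    return out


def decode(indices: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in indices)
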