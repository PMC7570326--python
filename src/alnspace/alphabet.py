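"""Canonical residue alphabet and sequence normalization.

The alignment alphabet is the 20 standard amino acids plus ``X`` (unknown
residue) and ``-`` (gap).  Input is normalized to uppercase and ``.`` gaps
are rewritten to ``-`` so that downstream code sees a single gap character.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN: str = "X"
GAP: str = "-"
ALPHABET: str = AMINO_ACIDS + UNKNOWN + GAP

#: integer codes used by the vectorized kernels
AA_CODES = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
X_CODE = len(AMINO_ACIDS)        # 20
GAP_CODE = len(AMINO_ACIDS) + 1  # 21
CHAR_CODES = {**AA_CODES, UNKNOWN: X_CODE, GAP: GAP_CODE}
CODE_CHARS = np.array(list(ALPHABET), dtype="U1")

_NORMALIZE = str.maketrans("." + "abcdefghijklmnopqrstuvwxyz",
                           "-" + "ABCDEFGHIJKLMNOPQRSTUVWXYZ")

# byte-value -> code lookup used by encode()
_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _ch, _code in CHAR_CODES.items():
    _CODE_LUT[ord(_ch)] = _code


def normalize(seq: str) -> str:
    """Uppercase a sequence and rewrite ``.`` gaps to ``-``."""
    return seq.translate(_NORMALIZE)


def invalid_chars(seq: str) -> set[str]:
    """Characters of a (normalized) sequence outside the canonical alphabet."""
    return set(seq) - set(ALPHABET)


def encode(seqs: list[str]) -> np.ndarray:
    """Encode equal-length normalized sequences as an (N, L) int8 code matrix.

    Codes 0..19 are the amino acids in :data:`AMINO_ACIDS` order, 20 is
    ``X`` and 21 the gap.
    """
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    codes = _CODE_LUT[buf].reshape(len(seqs), len(seqs[0]))
    if (codes < 0).any():
        bad = sorted({chr(b) for b in buf[_CODE_LUT[buf] < 0]})
        raise ValueError(f"characters outside alphabet: {bad}")
    return codes
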