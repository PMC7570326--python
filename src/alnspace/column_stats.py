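"""Per-column alignment statistics.

For each alignment column this module tallies residue counts, gap and
``X`` counts, amino-acid frequencies (gaps and ``X`` excluded from the
denominator), Shannon entropy and information content in bits, the
consensus residue, and sequence-logo letter heights.

Information content follows the standard sequence-logo convention with a
uniform background over the 20 amino acids:

    H(c)    = -sum_a p_a(c) * log2 p_a(c)
    info(c) = log2(20) - H(c),            clamped to >= 0

so a fully conserved column carries log2(20) ~ 4.3219 bits and a column
with all 20 residues equally frequent carries 0 bits.  Logo letter heights
are ``p_a(c) * info(c)`` and sum to the column information.  No
small-sample correction is applied by default: the statistics describe the
alignment as given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import alphabet
from .errors import EmptyMaskError
from .msa_io import Alignment

MAX_BITS: float = float(np.log2(len(alphabet.AMINO_ACIDS)))


@dataclass(frozen=True)
class ReferenceMask:
    """Columns kept after masking out reference-row gaps.

    ``columns`` are the kept 0-based alignment columns, ascending;
    ``ref_positions[k]`` is the 1-based ungapped reference position shown
    at kept-column ordinal ``k``.
    """

    columns: list[int]
    ref_positions: list[int]

    def __len__(self) -> int:
        return len(self.columns)

    def ordinal_of_ref_position(self, pos: int) -> int | None:
        """Kept-column ordinal displaying 1-based reference position ``pos``.

        Returns None when that reference position was masked out (cannot
        happen for positions produced by this mask) or out of range.
        """
        try:
            return self.ref_positions.index(pos)
        except ValueError:
            return None


@dataclass
class ColumnProfile:
    """Statistics of one alignment column."""

    col_index: int
    counts: dict[str, int]
    gap_count: int
    x_count: int
    freqs: dict[str, float]
    entropy_bits: float
    info_bits: float
    consensus: str
    logo_heights: dict[str, float]


def reference_mask(aln: Alignment) -> ReferenceMask:
    """Columns where the reference row carries a residue (non-gap).

    Mirrors the default display convention: columns gapped in the reference
    are omitted so positions line up with the reference's own coordinates.
    """
    ref = aln.reference
    columns = [c for c, ch in enumerate(ref) if ch != alphabet.GAP]
    if not columns:
        raise EmptyMaskError("reference sequence is entirely gaps")
    return ReferenceMask(columns=columns,
                         ref_positions=list(range(1, len(columns) + 1)))


def column_profiles(aln: Alignment,
                    mask: ReferenceMask | list[int] | None = None) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per kept column (all columns when no mask)."""
    columns = _mask_columns(aln, mask)
    codes = aln.codes()[:, columns]                    # (N, K)
    n_kinds = len(alphabet.ALPHABET)                   # 20 AA + X + gap
    tallies = np.zeros((len(columns), n_kinds), dtype=np.int64)
    for kind in range(n_kinds):
        tallies[:, kind] = (codes == kind).sum(axis=0)

    profiles: list[ColumnProfile] = []
    aa = alphabet.AMINO_ACIDS
    for k, col in enumerate(columns):
        counts_vec = tallies[k, : len(aa)]
        total = int(counts_vec.sum())
        counts = {aa[i]: int(counts_vec[i]) for i in range(len(aa))
                  if counts_vec[i] > 0}
        if total > 0:
            p = counts_vec[counts_vec > 0] / total
            entropy = float(-(p * np.log2(p)).sum())
            info = max(0.0, MAX_BITS - entropy)
            freqs = {r: c / total for r, c in counts.items()}
            # alphabetical tie-break: first max in A..Y order
            consensus = aa[int(np.argmax(counts_vec))]
            logo = {r: f * info for r, f in freqs.items()}
        else:
            entropy, info = 0.0, 0.0
            freqs, logo = {}, {}
            consensus = alphabet.GAP
        profiles.append(ColumnProfile(
            col_index=int(col),
            counts=counts,
            gap_count=int(tallies[k, alphabet.GAP_CODE]),
            x_count=int(tallies[k, alphabet.X_CODE]),
            freqs=freqs,
            entropy_bits=entropy,
            info_bits=info,
            consensus=consensus,
            logo_heights=logo,
        ))
    return profiles


def consensus_sequence(profiles: list[ColumnProfile]) -> str:
    """Most frequent residue per column; ties alphabetical; all-gap -> ``-``."""
    if not profiles:
        raise ValueError("profiles must be non-empty")
    return "".join(p.consensus for p in profiles)


def gap_fraction_per_sequence(aln: Alignment,
                              mask: ReferenceMask | list[int] | None = None) -> np.ndarray:
    """Per-sequence fraction of gap characters over the kept columns."""
    columns = _mask_columns(aln, mask)
    codes = aln.codes()[:, columns]
    return (codes == alphabet.GAP_CODE).mean(axis=1)


def _mask_columns(aln: Alignment,
                  mask: ReferenceMask | list[int] | None) -> list[int]:
    if mask is None:
        return list(range(aln.n_cols))
    columns = mask.columns if isinstance(mask, ReferenceMask) else list(mask)
    if not columns:
        raise ValueError("column mask must be non-empty")
    if any(not 0 <= c < aln.n_cols for c in columns):
        raise ValueError("mask contains out-of-range columns")
    return columns
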