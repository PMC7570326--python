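"""Sequence-level similarity metrics.

Two families of quantities:

* **Percent identity, gaps not counted.**  Matches are columns where two
  rows carry the same amino acid (``X`` never matches anything, itself
  included).  Reference-relative identity supports the two denominator
  conventions: the residue count of the *first* (reference) sequence or of
  the *second* (query) sequence.  The all-vs-all matrix divides by the
  count of mutually non-gap columns, which makes it symmetric.

* **Hamming distance.**  The number of alignment columns where two rows
  disagree, comparing the full aligned strings: gap vs residue is a
  difference, gap vs gap is equal, ``X`` vs ``X`` is equal.  This is the
  distance handed to the sequence-space embedding.

Both matrices are computed with one-hot matrix products over integer
residue codes, which keeps thousands of sequences tractable on one CPU;
results are exactly the naive per-character tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import alphabet
from .errors import UndefinedIdentityError
from .msa_io import Alignment

logger = logging.getLogger(__name__)


@dataclass
class PairwiseMatrix:
    """N x N symmetric matrix of percent identity or Hamming distance."""

    kind: str                 # "identity_percent" | "hamming"
    values: np.ndarray
    order: list[int]          # alignment row indices the rows/cols follow

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("pairwise matrix must be square")
        if self.kind not in ("identity_percent", "hamming"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class IdentitySummary:
    """Identity-to-reference vector with its min/max/mean."""

    per_sequence: np.ndarray
    min: float
    max: float
    mean: float


def _columns(aln: Alignment, columns) -> np.ndarray:
    codes = aln.codes()
    if columns is None:
        return codes
    cols = list(columns.columns) if hasattr(columns, "columns") else list(columns)
    return codes[:, cols]


def identity_to_reference(aln: Alignment, seq_index: int,
                          denominator: str = "first",
                          columns=None) -> float:
    """Percent identity of one row against the reference, gaps not counted.

    ``denominator='first'`` divides the match count by the number of
    reference residues; ``'second'`` divides by the number of residues of
    the compared sequence.
    """
    if denominator not in ("first", "second"):
        raise ValueError(f"denominator must be 'first' or 'second', got {denominator!r}")
    codes = _columns(aln, columns)
    ref = codes[aln.reference_index]
    row = codes[seq_index]
    matches = int(np.count_nonzero(
        (ref == row) & (ref < alphabet.X_CODE)))  # same residue, not X/gap
    denom_row = ref if denominator == "first" else row
    denom = int(np.count_nonzero(denom_row != alphabet.GAP_CODE))
    if denom == 0:
        which = aln.ids[aln.reference_index if denominator == "first" else seq_index]
        raise UndefinedIdentityError(
            f"denominator sequence {which!r} has no residues")
    return 100.0 * matches / denom


def identity_summary(aln: Alignment, denominator: str = "first",
                     columns=None) -> IdentitySummary:
    """Identity of every row (reference included) against the reference."""
    per_seq = np.array([
        identity_to_reference(aln, i, denominator, columns=columns)
        for i in range(aln.n_seqs)
    ])
    return IdentitySummary(per_sequence=per_seq,
                           min=float(per_seq.min()),
                           max=float(per_seq.max()),
                           mean=float(per_seq.mean()))


def pairwise_identity_matrix(aln: Alignment, columns=None) -> PairwiseMatrix:
    """All-vs-all percent identity over mutually non-gap columns.

    Entry (p, q) is ``100 * matches / overlap`` with overlap the number of
    columns where both rows carry a residue (``X`` included in the
    denominator but never a match).  Pairs with zero overlap get 0.0 with a
    logged warning.  The diagonal of a sequence containing ``X`` is below
    100 by this convention, so it is pinned to 100 explicitly (a sequence
    is always fully identical to itself).
    """
    if aln.n_seqs < 2:
        raise ValueError("pairwise identity needs at least 2 sequences")
    codes = _columns(aln, columns)
    onehot = _one_hot(codes, alphabet.X_CODE)             # AAs only
    matches = onehot @ onehot.T
    nongap = (codes != alphabet.GAP_CODE).astype(np.float32)
    overlap = nongap @ nongap.T
    zero = overlap == 0
    if zero.any():
        logger.warning("%d sequence pairs share no non-gap columns; identity set to 0",
                       int(np.count_nonzero(zero) // 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(zero, 0.0, 100.0 * matches / np.maximum(overlap, 1.0))
    np.fill_diagonal(ident, 100.0)
    return PairwiseMatrix(kind="identity_percent", values=ident.astype(np.float64),
                          order=list(range(aln.n_seqs)))


def hamming_matrix(aln: Alignment, columns=None) -> PairwiseMatrix:
    """All-vs-all Hamming distance over the full aligned strings."""
    if aln.n_seqs < 2:
        raise ValueError("hamming matrix needs at least 2 sequences")
    codes = _columns(aln, columns)
    onehot = _one_hot(codes, len(alphabet.ALPHABET))      # every symbol
    agree = onehot @ onehot.T
    n_cols = codes.shape[1]
    values = np.rint(n_cols - agree).astype(np.int64)
    np.fill_diagonal(values, 0)
    return PairwiseMatrix(kind="hamming", values=values,
                          order=list(range(aln.n_seqs)))


def _one_hot(codes: np.ndarray, n_kinds: int) -> np.ndarray:
    """(N, L*n_kinds) float32 one-hot of codes below ``n_kinds``."""
    n, length = codes.shape
    out = np.zeros((n, length * n_kinds), dtype=np.float32)
    rows = np.repeat(np.arange(n), length)
    flat = codes.ravel()
    keep = flat < n_kinds
    cols = np.tile(np.arange(length), n) * n_kinds + flat
    out[rows[keep], cols[keep]] = 1.0
    return out
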