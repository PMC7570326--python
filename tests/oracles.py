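"""Naive per-character reference implementations used as test oracles.

Everything here is a direct transliteration of the definitions: explicit
Python loops over characters, independent of the vectorized kernels they
check.
"""

from __future__ import annotations

import math

AA = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


def column_counts(seqs: list[str], col: int) -> tuple[dict[str, int], int, int]:
    """(amino-acid counts, gap count, X count) for one column."""
    counts: dict[str, int] = {}
    gaps = xs = 0
    for s in seqs:
        ch = s[col]
        if ch == GAP:
            gaps += 1
        elif ch == "X":
            xs += 1
        else:
            counts[ch] = counts.get(ch, 0) + 1
    return counts, gaps, xs


def column_info_bits(seqs: list[str], col: int) -> float:
    counts, _, _ = column_counts(seqs, col)
    total = sum(counts.values())
    if total == 0:
        return 0.0
    entropy = -sum((c / total) * math.log2(c / total) for c in counts.values())
    return max(0.0, math.log2(20) - entropy)


def gap_fraction(seq: str) -> float:
    return sum(ch == GAP for ch in seq) / len(seq)


def identity(ref: str, seq: str, denominator: str) -> float:
    matches = sum(a == b and a in AA for a, b in zip(ref, seq))
    denom_seq = ref if denominator == "first" else seq
    denom = sum(ch != GAP for ch in denom_seq)
    return 100.0 * matches / denom


def pairwise_identity(a: str, b: str) -> float:
    matches = overlap = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            overlap += 1
            if x == y and x in AA:
                matches += 1
    return 100.0 * matches / overlap if overlap else 0.0


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))
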