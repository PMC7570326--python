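"""Deterministic synthetic protein-family generator.

Emulates the structure of a mid-sized domain family: a random root
sequence, one ancestor per subfamily obtained by substituting each root
column with probability ``root_divergence``, and subfamily members derived
from their ancestor with per-column substitution probability
``within_divergence`` plus per-character gapping.  Substitutions are drawn
uniformly over the 19 alternative residues, and gaps replace characters in
place, so the alignment shape is fixed — the generator emulates the
*aligned* families the tool consumes, not an evolutionary indel process.

The first generated sequence is kept gapless and serves as the reference
row.  The true subfamily label of every sequence is returned as an
annotation table, which makes cluster-structure assertions possible
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from . import alphabet
from .msa_io import Alignment, AnnotationTable, CouplingSet


@dataclass
class FamilySpec:
    """Parameters of a synthetic family.

    Defaults describe the three-subfamily benchmark used throughout the
    test-suite: 3 x 40 sequences of 80 columns, ancestors ~50% diverged,
    members ~5% diverged within a subfamily, 3% gap characters.
    """

    n_subfamilies: int = 3
    seqs_per_subfamily: int = 40
    n_cols: int = 80
    root_divergence: float = 0.5
    within_divergence: float = 0.05
    gap_prob: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subfamilies < 1 or self.seqs_per_subfamily < 1 or self.n_cols < 1:
            raise ValueError("counts must be positive")
        for name in ("root_divergence", "within_divergence", "gap_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_subfamilies > 1 and not self.within_divergence < self.root_divergence:
            raise ValueError("within_divergence must be below root_divergence "
                             "for subfamilies to be separable")


def _mutate(rng: np.random.Generator, seq: np.ndarray, p: float) -> np.ndarray:
    """Substitute each column with probability p, uniform over the 19 others."""
    out = seq.copy()
    hit = rng.random(seq.size) < p
    n_aa = len(alphabet.AMINO_ACIDS)
    # uniform over the 19 alternatives: shift by 1..19 modulo 20
    out[hit] = (out[hit] + rng.integers(1, n_aa, hit.sum())) % n_aa
    return out


def generate_family(spec: FamilySpec) -> tuple[Alignment, AnnotationTable]:
    """Generate an alignment plus its true subfamily labels; seeded, deterministic."""
    rng = np.random.default_rng(spec.seed)
    n_aa = len(alphabet.AMINO_ACIDS)
    root = rng.integers(0, n_aa, spec.n_cols)
    ancestors = [_mutate(rng, root, spec.root_divergence)
                 for _ in range(spec.n_subfamilies)]

    ids: list[str] = []
    seqs: list[str] = []
    labels: list[str] = []
    first = True
    for s, anc in enumerate(ancestors, start=1):
        for m in range(1, spec.seqs_per_subfamily + 1):
            member = _mutate(rng, anc, spec.within_divergence)
            chars = alphabet.CODE_CHARS[member].copy()
            if first:
                first = False  # reference row stays gapless
            else:
                gapped = rng.random(spec.n_cols) < spec.gap_prob
                chars[gapped] = alphabet.GAP
            ids.append(f"sub{s}_seq{m}")
            seqs.append("".join(chars))
            labels.append(f"subfamily_{s}")
    aln = Alignment(ids=ids, seqs=seqs)
    table = AnnotationTable(data=pd.DataFrame({"subfamily": labels},
                                              index=pd.Index(ids, name="id")))
    return aln, table


def generate_couplings(n_ref_positions: int, n_pairs: int, seed: int = 0) -> CouplingSet:
    """Random unique position pairs with heavy-tailed (standard lognormal) scores."""
    max_pairs = n_ref_positions * (n_ref_positions - 1) // 2
    if n_pairs > max_pairs:
        raise ValueError(
            f"n_pairs={n_pairs} exceeds the {max_pairs} possible pairs "
            f"over {n_ref_positions} positions")
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    rng = np.random.default_rng(seed)
    all_pairs = list(combinations(range(1, n_ref_positions + 1), 2))
    chosen = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    scores = rng.lognormal(mean=0.0, sigma=1.0, size=n_pairs)
    pairs = sorted((all_pairs[c][0], all_pairs[c][1], float(s))
                   for c, s in zip(chosen, scores))
    return CouplingSet(pairs=pairs)
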