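import numpy as np
import pytest

from alnspace import Alignment, FamilySpec, generate_family
from alnspace.alphabet import AMINO_ACIDS, GAP


@pytest.fixture
def toy_alignment() -> Alignment:
    """Four sequences with hand-computable identities vs the reference.

    Identities to the reference (denominator=first, 8 residue columns):
    ref 100%, s2 6/8 = 75%, s3 4/8 = 50%, s4 2/8 = 25%.
    """
    return Alignment(
        ids=["ref", "s2", "s3", "s4"],
        seqs=[
            "ACDEFGHI",
            "ACDEFG--",   # 6 matches, 2 gaps
            "ACDE----",   # 4 matches
            "AC--WYWY",   # 2 matches
        ],
    )


@pytest.fixture
def family():
    """Default 3-subfamily benchmark family (120 x 80, seed 11)."""
    return generate_family(FamilySpec(seed=11))


def random_alignment(rng: np.random.Generator, n_seqs: int = 8,
                     n_cols: int = 12, gap_prob: float = 0.15,
                     x_prob: float = 0.05) -> Alignment:
    """Random alignment over the full alphabet; the reference row is gapless."""
    chars = np.array(list(AMINO_ACIDS + "X" + GAP))
    probs = np.full(22, (1 - gap_prob - x_prob) / 20)
    probs[20] = x_prob
    probs[21] = gap_prob
    rows = []
    for i in range(n_seqs):
        draw = rng.choice(22, size=n_cols, p=probs)
        if i == 0:
            draw[draw >= 20] = rng.integers(0, 20, (draw >= 20).sum())
        rows.append("".join(chars[draw]))
    return Alignment(ids=[f"r{i}" for i in range(n_seqs)], seqs=rows)
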