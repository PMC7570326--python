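"""Row sorting and filtering of alignments.

Four sort modes: original order, identity to the reference under either
denominator convention, or a user-provided numeric annotation.  Two
filters: identity-to-reference bounds (inclusive) and a maximum gap
fraction.  In every mode the reference row is pinned first and exempt from
filtering — it anchors every downstream statistic and view.  Sorts are
stable: ties keep original relative order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import column_stats, seq_metrics
from .msa_io import Alignment, AnnotationTable

SORT_MODES = ("original", "identity_denominator_first",
              "identity_denominator_second", "annotation")


@dataclass
class SortSpec:
    """How to order alignment rows (below the pinned reference row)."""

    mode: str = "original"
    annotation_key: str | None = None
    descending: bool = True

    def __post_init__(self) -> None:
        if self.mode not in SORT_MODES:
            raise ValueError(f"unknown sort mode {self.mode!r}")
        if (self.mode == "annotation") != (self.annotation_key is not None):
            raise ValueError("annotation_key is required exactly when mode='annotation'")


@dataclass
class FilterSpec:
    """Row-retention bounds; unset bounds are no-ops."""

    min_identity: float | None = None
    max_identity: float | None = None
    max_gap_fraction: float | None = None

    def __post_init__(self) -> None:
        for bound in (self.min_identity, self.max_identity):
            if bound is not None and not 0.0 <= bound <= 100.0:
                raise ValueError(f"identity bound {bound} outside [0, 100]")
        if self.max_gap_fraction is not None and not 0.0 <= self.max_gap_fraction <= 1.0:
            raise ValueError(f"max_gap_fraction {self.max_gap_fraction} outside [0, 1]")
        if (self.min_identity is not None and self.max_identity is not None
                and self.min_identity > self.max_identity):
            raise ValueError("min_identity exceeds max_identity")


class MissingAnnotationError(ValueError):
    """Annotation sort requested but some alignment ids lack values."""


def sort_sequences(aln: Alignment, spec: SortSpec,
                   annotations: AnnotationTable | None = None,
                   columns=None) -> list[int]:
    """Stable permutation of row indices; the reference row comes first."""
    others = [i for i in range(aln.n_seqs) if i != aln.reference_index]
    if spec.mode == "original":
        return [aln.reference_index] + others
    if spec.mode in ("identity_denominator_first", "identity_denominator_second"):
        denom = "first" if spec.mode.endswith("first") else "second"
        key = {i: seq_metrics.identity_to_reference(aln, i, denom, columns=columns)
               for i in others}
    else:  # annotation
        if annotations is None:
            raise ValueError("annotation sort requires an AnnotationTable")
        if spec.annotation_key not in annotations.columns:
            raise KeyError(f"annotation {spec.annotation_key!r} not found")
        if not annotations.is_numeric(spec.annotation_key):
            raise TypeError(
                f"annotation {spec.annotation_key!r} is categorical; "
                "only numeric attributes can be sorted on")
        vals = annotations.values_for(spec.annotation_key,
                                      [aln.ids[i] for i in others])
        missing = [aln.ids[i] for i, v in zip(others, vals) if np.isnan(v)]
        if missing:
            raise MissingAnnotationError(
                f"no {spec.annotation_key!r} value for ids: {missing}")
        key = dict(zip(others, vals))
    ordered = sorted(others, key=lambda i: -key[i] if spec.descending else key[i])
    return [aln.reference_index] + ordered


def filter_sequences(aln: Alignment, spec: FilterSpec,
                     denominator: str = "first",
                     columns=None) -> list[int]:
    """Row indices passing the filters, original order; reference always kept."""
    if spec.max_gap_fraction is not None:
        gaps = column_stats.gap_fraction_per_sequence(aln, mask=columns)
    retained = []
    for i in range(aln.n_seqs):
        if i == aln.reference_index:
            retained.append(i)
            continue
        if spec.min_identity is not None or spec.max_identity is not None:
            ident = seq_metrics.identity_to_reference(aln, i, denominator,
                                                      columns=columns)
            if spec.min_identity is not None and ident < spec.min_identity:
                continue
            if spec.max_identity is not None and ident > spec.max_identity:
                continue
        if spec.max_gap_fraction is not None and gaps[i] > spec.max_gap_fraction:
            continue
        retained.append(i)
    return retained
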