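"""Readers and writers for alignments, per-sequence annotations and couplings.

Formats
-------
* aligned FASTA (``>`` headers, wrapped or unwrapped) via Biopython;
* plain MSA text: one sequence per line, or ``id <whitespace> sequence``;
* annotations: delimited text (TSV/CSV) with a header row and an id column;
* couplings: delimited text with columns ``i``, ``j``, ``score`` holding
  1-based positions in the ungapped reference coordinate system (the
  convention used by evolutionary-couplings pipelines such as EVcouplings).

All sequence input is normalized on read: uppercased, ``.`` gaps rewritten
to ``-``.  Sequence order is preserved exactly as given.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import alphabet
from .errors import (
    AlignmentShapeError,
    AlphabetError,
    CouplingPositionError,
    DuplicateIdError,
    EmptyInputError,
    SchemaError,
    SelfCouplingError,
)

logger = logging.getLogger(__name__)

Source = Union[str, os.PathLike, TextIO]


@dataclass
class Alignment:
    """An ordered protein multiple sequence alignment.

    The first row (``reference_index=0`` by default) is the reference
    sequence: the anchor for column masking, identity calculations and
    position reporting.
    """

    ids: list[str]
    seqs: list[str]
    reference_index: int = 0
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentShapeError(
                f"{len(self.ids)} ids but {len(self.seqs)} sequences")
        if not self.seqs:
            raise EmptyInputError("alignment must contain at least one sequence")
        n_cols = len(self.seqs[0])
        if n_cols < 1:
            raise AlignmentShapeError("sequences must have at least one column")
        for sid, seq in zip(self.ids, self.seqs):
            if len(seq) != n_cols:
                raise AlignmentShapeError(
                    f"sequence {sid!r} has length {len(seq)}, expected {n_cols}")
            bad = alphabet.invalid_chars(seq)
            if bad:
                raise AlphabetError(
                    f"sequence {sid!r} contains characters outside the "
                    f"alphabet: {sorted(bad)}")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))
            raise DuplicateIdError(f"duplicate sequence id {dup!r}")
        if not 0 <= self.reference_index < len(self.seqs):
            raise IndexError("reference_index out of range")

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0])

    @property
    def reference(self) -> str:
        return self.seqs[self.reference_index]

    def codes(self) -> np.ndarray:
        """(N, L) int8 residue-code matrix; cached after first use."""
        if self._codes is None:
            self._codes = alphabet.encode(self.seqs)
        return self._codes

    def take(self, indices: Iterable[int]) -> "Alignment":
        """New alignment with the given rows, in the given order.

        The reference row must be among ``indices``; its new position
        becomes the new ``reference_index``.
        """
        idx = list(indices)
        if self.reference_index not in idx:
            raise ValueError("take() must retain the reference row")
        return Alignment(ids=[self.ids[i] for i in idx],
                         seqs=[self.seqs[i] for i in idx],
                         reference_index=idx.index(self.reference_index))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (self.ids == other.ids and self.seqs == other.seqs
                and self.reference_index == other.reference_index)


@dataclass
class AnnotationTable:
    """Per-sequence attributes keyed by sequence identifier.

    Columns are either numeric (every non-missing value parses as a real
    number) or categorical (label strings).  Keys need not match any
    particular alignment at read time.
    """

    data: pd.DataFrame  # indexed by sequence id

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DuplicateIdError(f"duplicate annotation id {dup!r}")

    @property
    def keys(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def is_numeric(self, column: str) -> bool:
        return pd.api.types.is_numeric_dtype(self.data[column])

    def values_for(self, column: str, ids: Iterable[str]) -> pd.Series:
        """Column values aligned to ``ids`` (NaN/None where missing)."""
        return self.data[column].reindex(list(ids))


@dataclass
class CouplingSet:
    """Scored pairs of reference positions (1-based, ungapped coordinates)."""

    pairs: list[tuple[int, int, float]]

    def top(self, k: int) -> list[tuple[int, int, float]]:
        """The ``k`` highest-scoring pairs, descending by score."""
        return sorted(self.pairs, key=lambda p: (-p[2], p[0], p[1]))[:k]

    def validate_positions(self, ref_length: int) -> None:
        for i, j, _ in self.pairs:
            if not (1 <= i <= ref_length and 1 <= j <= ref_length):
                raise CouplingPositionError(
                    f"coupling ({i}, {j}) outside reference length {ref_length}")


# ---------------------------------------------------------------------------
# alignment I/O

def _as_text(source: Source) -> str:
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text()


def _sniff_format(text: str) -> str:
    for line in text.splitlines():
        if line.strip():
            return "fasta" if line.lstrip().startswith(">") else "msa_text"
    raise EmptyInputError("input contains no sequences")


def read_alignment(source: Source, format: str = "auto") -> Alignment:
    """Read an alignment from FASTA or plain MSA text.

    ``format='auto'`` sniffs: a leading ``>`` means FASTA, anything else is
    treated as MSA text (one sequence per line, optionally preceded by an
    identifier and whitespace).  Sequences are normalized (uppercase,
    ``.`` -> ``-``) and order is preserved.
    """
    text = _as_text(source)
    if format == "auto":
        format = _sniff_format(text)
    if format == "fasta":
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not records:
            raise EmptyInputError("no FASTA records found")
        ids = [r.id for r in records]
        seqs = [alphabet.normalize(str(r.seq)) for r in records]
    elif format == "msa_text":
        ids, seqs = _parse_msa_text(text)
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return Alignment(ids=ids, seqs=seqs)


def _parse_msa_text(text: str) -> tuple[list[str], list[str]]:
    """Parse one-sequence-per-line MSA text.

    A line is either a bare sequence or ``id <whitespace> sequence``; the
    two-token layout is assumed when splitting yields exactly two tokens and
    the second one normalizes to alphabet characters only.
    """
    rows: list[tuple[str | None, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) == 2 and not alphabet.invalid_chars(alphabet.normalize(tokens[1])):
            rows.append((tokens[0], alphabet.normalize(tokens[1])))
        elif len(tokens) == 1:
            rows.append((None, alphabet.normalize(tokens[0])))
        else:
            raise AlignmentShapeError(
                f"cannot parse MSA text line: {line[:60]!r}")
    if not rows:
        raise EmptyInputError("input contains no sequences")
    if any(rid is not None for rid, _ in rows) and any(rid is None for rid, _ in rows):
        raise AlignmentShapeError("mixed id/no-id lines in MSA text")
    ids = [rid if rid is not None else f"seq_{k}"
           for k, (rid, _) in enumerate(rows, start=1)]
    return ids, [seq for _, seq in rows]


def write_alignment(aln: Alignment, sink: Source, format: str = "fasta") -> None:
    """Write an alignment as unwrapped aligned FASTA, preserving order."""
    if format != "fasta":
        raise ValueError(f"unsupported output format {format!r}")
    records = [SeqRecord(Seq(s), id=i, description="")
               for i, s in zip(aln.ids, aln.seqs)]
    if hasattr(sink, "write"):
        SeqIO.write(records, sink, "fasta-2line")
    else:
        with open(sink, "w") as handle:
            SeqIO.write(records, handle, "fasta-2line")


# ---------------------------------------------------------------------------
# annotations

def read_annotations(source: Source, id_column: str = "id",
                     delimiter: str | None = None) -> AnnotationTable:
    """Read a per-sequence annotation table from delimited text.

    The file must have a header row containing ``id_column``.  Columns whose
    non-missing values all parse as real numbers become numeric; all others
    are kept as categorical labels.  ``delimiter=None`` sniffs comma vs tab.
    """
    text = _as_text(source)
    if delimiter is None:
        header = text.splitlines()[0] if text.splitlines() else ""
        delimiter = "\t" if "\t" in header else ","
    df = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str,
                     skipinitialspace=True)
    if id_column not in df.columns:
        raise SchemaError(
            f"id column {id_column!r} not found; columns are {list(df.columns)}")
    df = df.set_index(id_column)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        non_missing = df[col].notna()
        if non_missing.any() and numeric[non_missing].notna().all():
            df[col] = numeric
    return AnnotationTable(data=df)


# ---------------------------------------------------------------------------
# couplings

def read_couplings(source: Source, delimiter: str = ",") -> CouplingSet:
    """Read an evolutionary-couplings table (columns ``i``, ``j``, ``score``).

    Pairs are canonicalized to ``i < j``; duplicated unordered pairs are
    collapsed keeping the highest score, with a logged warning.  A row with
    ``i == j`` is rejected.
    """
    text = _as_text(source)
    df = pd.read_csv(io.StringIO(text), sep=delimiter, skipinitialspace=True)
    missing = {"i", "j", "score"} - set(df.columns)
    if missing:
        raise SchemaError(f"couplings table missing columns {sorted(missing)}")
    try:
        ii = df["i"].astype(int)
        jj = df["j"].astype(int)
        scores = df["score"].astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"couplings table has non-numeric values: {exc}") from exc
    if scores.isna().any():
        raise SchemaError("couplings table has missing scores")
    best: dict[tuple[int, int], float] = {}
    for i, j, s in zip(ii, jj, scores):
        if i == j:
            raise SelfCouplingError(f"position {i} coupled with itself")
        key = (min(i, j), max(i, j))
        if key in best:
            logger.warning("duplicate coupling pair %s; keeping highest score", key)
            best[key] = max(best[key], float(s))
        else:
            best[key] = float(s)
    pairs = [(i, j, s) for (i, j), s in sorted(best.items())]
    return CouplingSet(pairs=pairs)
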