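"""Exception hierarchy.

``AlnspaceError`` covers data-level problems (exit code 2 at the CLI);
plain ``ValueError``/``TypeError`` are reserved for caller mistakes.
"""


class AlnspaceError(Exception):
    """Base class for data errors raised by this package."""


class AlignmentShapeError(AlnspaceError):
    """Sequences in an alignment do not all share the same length."""


class AlphabetError(AlnspaceError):
    """A sequence contains characters outside the amino-acid alphabet."""


class EmptyInputError(AlnspaceError):
    """An input source contained no records."""


class DuplicateIdError(AlnspaceError):
    """An identifier occurs more than once where uniqueness is required."""


class SchemaError(AlnspaceError):
    """A delimited-text input is missing required columns."""


class SelfCouplingError(AlnspaceError):
    """A couplings row pairs a position with itself."""


class CouplingPositionError(AlnspaceError):
    """A coupling references a position beyond the reference length."""


class EmptyMaskError(AlnspaceError):
    """The reference row is entirely gaps; no columns can be displayed."""


class UndefinedIdentityError(AlnspaceError):
    """Percent identity is undefined because the denominator sequence has no residues."""
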