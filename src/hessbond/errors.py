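"""Exception and warning hierarchy.

All package errors derive from :class:`HessbondError` so callers can catch
one base class; warnings derive from :class:`HessbondWarning` and are
collected per term by :func:`hessbond.gromacs_out.derive_all`.
"""

from __future__ import annotations

__all__ = [
    "HessbondError",
    "FchkError",
    "FchkFormatError",
    "FchkTruncationError",
    "FchkParseError",
    "DimensionError",
    "GeometryError",
    "NonPositiveStiffnessError",
    "TermListError",
    "TermLookupError",
    "NonPhysicalParameterError",
    "HessbondWarning",
    "NoInteractionWarning",
    "NonMinimumWarning",
    "DuplicateTermWarning",
]


class HessbondError(Exception):
    """Base class for all errors raised by hessbond."""


class FchkError(HessbondError, ValueError):
    """Base class for formatted-checkpoint reading problems."""


class FchkFormatError(FchkError):
    """A required fchk section is missing or structurally inconsistent."""


class FchkTruncationError(FchkError):
    """A section declares more (or fewer) values than the file contains."""


class FchkParseError(FchkError):
    """A token could not be converted to a number.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class DimensionError(HessbondError, ValueError):
    """A flat array length is inconsistent with the requested matrix size."""


class GeometryError(HessbondError, ValueError):
    """Degenerate geometry: coincident atoms, zero-length arm, collinear angle."""


class NonPositiveStiffnessError(HessbondError, ValueError):
    """An arm of the angle formula produced a non-positive stiffness sum."""


class TermListError(HessbondError, ValueError):
    """A term-list line is malformed. Carries the 1-based line number."""

    def __init__(self, message: str, lineno: int):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


class TermLookupError(HessbondError, LookupError):
    """A term references an atom ID outside the parsed structure."""


class NonPhysicalParameterError(HessbondError, ValueError):
    """Refusal to emit a negative force constant to a topology file."""


class HessbondWarning(UserWarning):
    """Base class for all warnings emitted by hessbond."""


class NoInteractionWarning(HessbondWarning):
    """The requested atom pair has a (near-)zero Hessian coupling block."""


class NonMinimumWarning(HessbondWarning):
    """A projected stiffness came out non-positive.

    This happens when the structure is not at a true minimum or when an
    unrealistic atom pair/triplet was requested.
    """


class DuplicateTermWarning(HessbondWarning):
    """An identical term appeared more than once in the term list."""
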