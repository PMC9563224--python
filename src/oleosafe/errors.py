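"""Exception hierarchy.

Every error raised by oleosafe derives from :class:`OleosafeError`, so callers
can catch the package's failures with a single except clause while still
distinguishing parse problems (bad input text) from domain problems (a formula
evaluated outside its mathematical domain, e.g. a zero denominator).
"""


class OleosafeError(Exception):
    """Base class for all oleosafe errors."""


class ShorthandParseError(OleosafeError, ValueError):
    """A fatty-acid shorthand token does not match the C<chain>:<db>[n<f>][c|t] grammar."""


class ValidationError(OleosafeError, ValueError):
    """An input value violates a structural invariant (negative percent, lod > loq, ...)."""


class DomainError(OleosafeError, ArithmeticError):
    """A computation was requested outside its domain (zero denominator, empty panel)."""


class MissingSpeciesError(OleosafeError, KeyError):
    """A fatty-acid species referenced by shorthand is absent from the profile."""


class UnitMismatchError(OleosafeError, ValueError):
    """Measured value and rule carry different unit strings."""
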