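"""Typed exceptions shared across the package.

Data errors (bad files, bad counts) are distinct from numerical failures
(separation, zero slope) so the CLI can map them to distinct exit codes.
"""


class RepliLifeError(Exception):
    """Base class for all package errors."""


class DataError(RepliLifeError):
    """Malformed or invalid input data."""


class ParseError(DataError):
    """A file could not be parsed at all."""


class SchemaError(DataError):
    """A file parsed but violated the expected schema; carries line numbers."""


class EmptyInputError(DataError):
    """An operation requiring at least one (uncensored) event got none."""


class InsufficientDataError(DataError):
    """Fewer than two distinct timepoints — the two-parameter fit is undefined."""


class NumericalError(RepliLifeError):
    """A computation is undefined or unbounded for the given input."""


class SeparationError(NumericalError):
    """Deaths are perfectly separated in time; the binomial likelihood is unbounded."""


class ZeroSlopeError(NumericalError):
    """Logit slope a = 0: LD50 and maximum life are undefined."""


class ZeroReferenceError(NumericalError):
    """Percent change from a zero reference is undefined."""


class AlphabetError(DataError):
    """Sequence contains characters outside {A, C, G, T, N}."""


class MissingSequenceError(DataError):
    """A peak has no associated sequence."""


class NotInUniverseError(DataError):
    """A set element is missing from the stated universe."""


class DegenerateTableError(NumericalError):
    """A 2x2 contingency margin is zero; chi-squared is undefined."""


class CapacityError(DataError):
    """Synthetic genome cannot place the requested features within bounds."""


class NoGeneOnChromError(RepliLifeError):
    """A chromosome holds peaks but no genes; its peaks are skipped."""
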