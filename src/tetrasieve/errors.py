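"""Exception hierarchy shared across the package."""


class TetraSieveError(Exception):
    """Base class for all package errors."""


class InputError(TetraSieveError):
    """Unreadable, malformed, or otherwise invalid input."""


class EmptyGenomeError(InputError):
    """No sequence survived the minimum-length filter; the genome cannot be sieved."""


class TooShortGenomeError(TetraSieveError):
    """Processed genome below the minimum size eligible for dividing (10 kb)."""


class UndefinedCorrelationError(TetraSieveError):
    """Pearson correlation requested for a zero-variance vector."""


class CalibrationError(TetraSieveError):
    """Missing or unusable length-specific calibration data."""


class DeltaParseError(InputError):
    """Malformed NUCmer .delta file; message carries the offending line number."""


class ValidationError(TetraSieveError):
    """A requested operation violates a stated precondition or invariant."""
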