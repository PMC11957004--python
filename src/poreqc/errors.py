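"""Exception hierarchy for the nanopore QC pipeline."""


class PoreQCError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PoreQCError, ValueError):
    """A physical parameter violates its domain (non-positive length, etc.)."""


class OutOfRangeError(PoreQCError, ValueError):
    """A root search or inversion has no solution in the physical bracket."""


class FitFailureError(PoreQCError, RuntimeError):
    """All mixture-fit restarts collapsed onto degenerate components."""


class UndefinedFrequencyError(PoreQCError, ZeroDivisionError):
    """Event frequency requested over zero effective duration."""


class MarkerNotDetectedError(PoreQCError, ZeroDivisionError):
    """The internal 1 kbp marker produced no events; C_T = C_M * f_T / f_M is undefined.

    Check that the marker was spiked into the measurement buffer and that the
    mixture component covering the marker amplitude range is populated.
    """


class ChunkShortageError(PoreQCError, ValueError):
    """Not enough disjoint acquisition chunks for the requested pooling."""
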