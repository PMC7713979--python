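"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage errors exit 1, data validation
errors exit 2, numerical failures exit 3.
"""


class SeqEffortError(Exception):
    """Base class for all package errors."""


class ParameterError(SeqEffortError, ValueError):
    """An argument violates a precondition (bad range, wrong length, ...)."""


class DataValidationError(SeqEffortError, ValueError):
    """Input data fails structural validation (negative counts, bad files)."""


class NumericalError(SeqEffortError, RuntimeError):
    """A numerical procedure failed (no model converged, singular system)."""
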