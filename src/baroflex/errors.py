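"""Exception hierarchy shared across the pipeline.

Every failure mode the readers, detectors and spectral stages can hit maps
to one of these classes so callers can distinguish "your file is malformed"
from "this recording cannot support the analysis".
"""


class BaroflexError(Exception):
    """Base class for all package errors."""


class FormatError(BaroflexError):
    """Input file violates the documented on-disk dialect."""


class DataError(BaroflexError):
    """File parsed but contains values the pipeline cannot accept."""


class SignalQualityError(BaroflexError):
    """Raw signal too degraded (flat line, no breaths, ...) to analyze."""


class InsufficientDataError(BaroflexError):
    """Recording too short or too sparse for the requested stage."""


class ConfigurationError(BaroflexError):
    """Invalid analysis or simulation parameters."""


class SuitabilityError(BaroflexError):
    """Session rejected for analysis (e.g. frequent ectopy).

    Carries the measured ectopic fraction so callers can report why.
    """

    def __init__(self, message: str, ectopic_fraction: float | None = None):
        super().__init__(message)
        self.ectopic_fraction = ectopic_fraction
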