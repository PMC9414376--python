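"""Exception hierarchy for enosekit.

All library errors derive from :class:`EnosekitError` so callers (and the
CLI) can catch one base class.
"""


class EnosekitError(Exception):
    """Base class for all enosekit errors."""


class ValidationError(EnosekitError, ValueError):
    """An input value violates a documented precondition."""


class DimensionError(EnosekitError, ValueError):
    """Array shapes or channel counts do not line up."""


class WindowRangeError(EnosekitError, ValueError):
    """A requested time window extends beyond the recording span."""


class SizeError(EnosekitError, ValueError):
    """Too few rows/samples for the requested operation."""


class ParseError(EnosekitError, ValueError):
    """A recording or manifest file is malformed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(EnosekitError, ValueError):
    """Unknown or invalid configuration key/value."""


class BackendUnavailableError(EnosekitError, RuntimeError):
    """A classifier backend's underlying library is not installed."""
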