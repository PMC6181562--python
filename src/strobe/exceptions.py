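"""Exception hierarchy for the strobe package."""


class StrobeError(Exception):
    """Base class for all strobe errors."""


class InvalidParameterError(StrobeError, ValueError):
    """A parameter value violates its contract (e.g. non-positive sample period)."""


class SessionMismatchError(StrobeError, ValueError):
    """Two traces of a session disagree in length or sampling rate."""


class ConfigurationError(StrobeError, ValueError):
    """A configuration is inconsistent (duplicate channels, unknown fields, ...)."""


class InvalidInputError(StrobeError, ValueError):
    """An input trace or record cannot support the requested computation."""


class ParseError(StrobeError, ValueError):
    """A data file could not be parsed; the message names the offending row."""
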