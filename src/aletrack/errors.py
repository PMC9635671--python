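"""Exception hierarchy.

All aletrack errors derive from :class:`AletrackError` so callers can catch
the package's failures with one clause; subclasses map onto pipeline stages.
"""


class AletrackError(Exception):
    """Base class for all aletrack errors."""


class ConfigError(AletrackError, ValueError):
    """Invalid configuration value or combination."""


class ParameterError(AletrackError, ValueError):
    """Invalid parameter passed to an analysis operation."""


class LayoutError(AletrackError, ValueError):
    """Plate layout cannot host the requested design, or is inconsistent."""


class NormalizationError(AletrackError, RuntimeError):
    """A plate cannot be spatially normalized (e.g. too few usable references)."""


class SchemaError(AletrackError, ValueError):
    """An input table does not match the expected schema."""


class RecordError(AletrackError, ValueError):
    """A record-level validation failure (with location information)."""
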