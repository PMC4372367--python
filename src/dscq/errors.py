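"""Exception hierarchy for the dscq pipeline.

All errors derive from :class:`DscqError` so callers can catch pipeline
failures with a single except clause while still distinguishing bad user
parameters from bad data.
"""


class DscqError(Exception):
    """Base class for all dscq errors."""


class ParameterError(DscqError, ValueError):
    """A caller-supplied parameter is out of its valid domain."""


class ConfigurationError(DscqError, ValueError):
    """A configuration value (model name, region name, config key) is unknown."""


class DataError(DscqError, ValueError):
    """Input data violate an assumption (empty mask, zero-mass AIF, NaNs...)."""


class ShapeError(DscqError, ValueError):
    """Array shapes are inconsistent."""


class StateError(DscqError, RuntimeError):
    """An operation was applied in an invalid object state (e.g. double calibration)."""
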