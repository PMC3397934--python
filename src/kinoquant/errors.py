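"""Exception hierarchy.

``KinoquantError`` is the base; configuration/validation problems and I/O
problems are distinguished so the command line can map them to exit codes.
"""


class KinoquantError(Exception):
    """Base class for all package errors."""


class ConfigError(KinoquantError):
    """Invalid configuration (bad channel map, overlapping windows, ...)."""


class ParseError(KinoquantError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(KinoquantError):
    """A tabular input is missing required columns."""


class ValidationError(KinoquantError):
    """A value violates a contract (negative intensity, bad ratio, ...)."""


class NormalizationError(KinoquantError):
    """Channel normalization impossible (e.g. a zero-total channel)."""


class CalibrationError(KinoquantError):
    """Too little data to calibrate the noise model."""


class AggregationError(KinoquantError):
    """Protein-level aggregation called with no usable peptides."""
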